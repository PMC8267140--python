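"""Readers and writers for the package's external artifacts.

Four text formats cross the package boundary:

* expression matrices — TSV, genes in rows, first column the gene id,
  header row of sample ids (FPKM-like continuous values);
* clinical tables — TSV with a header, one row per sample, carrying
  survival time, event status and optional covariates;
* gene-set collections — standard GMT (name, description, members);
* signature models — JSON with an explicit schema version.

All loaders validate the invariants of the in-memory types they build and
fail loudly (naming offending identifiers) rather than silently repairing
input.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MODEL_SCHEMA_VERSION = 1

__all__ = [
    "ExpressionMatrix",
    "ClinicalTable",
    "GeneSetCollection",
    "SignatureModel",
    "read_expression",
    "write_expression",
    "read_clinical",
    "write_clinical",
    "read_gmt",
    "write_gmt",
    "read_model",
    "write_model",
]


@dataclass
class ExpressionMatrix:
    """Continuous gene-by-sample abundance values for one cohort.

    ``data`` is a genes x samples DataFrame whose index holds unique gene
    ids and whose columns hold unique sample ids.  Values are unitless
    continuous abundances (FPKM-like, or log-transformed).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        idx = self.data.index
        cols = self.data.columns
        if idx.has_duplicates:
            dups = sorted(idx[idx.duplicated()].unique())
            raise ValueError(f"duplicate gene ids: {dups}")
        if cols.has_duplicates:
            dups = sorted(cols[cols.duplicated()].unique())
            raise ValueError(f"duplicate sample ids: {dups}")
        if self.data.shape[0] < 2 or self.data.shape[1] < 2:
            raise ValueError(
                f"expression matrix needs >=2 genes and >=2 samples, "
                f"got {self.data.shape[0]} x {self.data.shape[1]}"
            )
        if self.data.isna().any().any():
            raise ValueError("expression matrix contains missing values")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        missing = [g for g in genes if g not in self.data.index]
        if missing:
            raise KeyError(f"genes absent from expression matrix: {missing}")
        return ExpressionMatrix(self.data.loc[list(genes)])


@dataclass
class ClinicalTable:
    """Per-sample survival time, event flag and covariates.

    ``data`` is a samples x variables DataFrame indexed by sample id with
    at least ``time`` (positive real, cohort-local unit) and ``event``
    (0/1) columns; additional covariates (age, sex, metastasis, ...) ride
    along untouched.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dups = sorted(self.data.index[self.data.index.duplicated()].unique())
            raise ValueError(f"duplicate sample ids: {dups}")
        for col in ("time", "event"):
            if col not in self.data.columns:
                raise ValueError(f"clinical table lacks required column '{col}'")
        if (self.data["time"] <= 0).any() or self.data["time"].isna().any():
            raise ValueError("clinical table contains non-positive or missing times")
        ev = self.data["event"]
        if ev.isna().any() or not ev.isin([0, 1]).all():
            raise ValueError("event column must be 0/1 with no missing values")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def time(self) -> pd.Series:
        return self.data["time"].astype(float)

    @property
    def event(self) -> pd.Series:
        return self.data["event"].astype(int)

    def subset(self, samples: Sequence[str]) -> "ClinicalTable":
        missing = [s for s in samples if s not in self.data.index]
        if missing:
            raise KeyError(f"samples absent from clinical table: {missing}")
        return ClinicalTable(self.data.loc[list(samples)])


@dataclass
class GeneSetCollection:
    """Named gene sets (pathways, marker panels) with optional descriptions."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        cleaned: dict[str, list[str]] = {}
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set '{name}' is empty")
            seen: set[str] = set()
            dedup = []
            for g in members:
                if g not in seen:
                    seen.add(g)
                    dedup.append(g)
            cleaned[name] = dedup
        self.sets = cleaned

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def names(self) -> list[str]:
        return list(self.sets)


@dataclass
class SignatureModel:
    """A fitted gene-pair risk signature.

    The risk score of a sample is the linear predictor
    ``sum_i coefficients[i] * I(expr[gene_a_i] > expr[gene_b_i])``;
    samples scoring strictly above ``cutoff`` are called high-risk.
    ``auroc_horizon`` records the time horizon (cohort-local units) at
    which the model's time-dependent AUC was evaluated during selection.
    """

    pairs: list[tuple[str, str]]
    coefficients: list[float]
    auroc_horizon: float
    cutoff: float
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pairs = [tuple(p) for p in self.pairs]
        self.coefficients = [float(c) for c in self.coefficients]
        if len(self.pairs) != len(self.coefficients) or not self.pairs:
            raise ValueError("need one coefficient per pair and at least one pair")
        for a, b in self.pairs:
            if a == b:
                raise ValueError(f"pair with identical genes: {a}")
        if self.auroc_horizon <= 0:
            raise ValueError("auroc_horizon must be positive")


def read_expression(path: str | Path, log2_transform: bool = False) -> ExpressionMatrix:
    """Load a TSV expression matrix (genes in rows, first column gene id).

    Rows containing any missing value are dropped (the count is logged);
    with ``log2_transform`` values become ``log2(x + 1)``.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dups = sorted(df.index[df.index.duplicated()].unique())
        raise ValueError(f"duplicate gene ids in {path}: {dups}")
    non_numeric = df.columns[
        [not np.issubdtype(dt, np.number) for dt in df.dtypes]
    ]
    for col in non_numeric:
        bad = df[col][pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()]
        if len(bad):
            raise ValueError(
                f"non-numeric value {bad.iloc[0]!r} at gene '{bad.index[0]}', "
                f"sample '{col}' in {path}"
            )
        df[col] = pd.to_numeric(df[col])
    n_missing = int(df.isna().any(axis=1).sum())
    if n_missing:
        logger.info("dropping %d gene rows with missing values from %s", n_missing, path)
        df = df.dropna(axis=0)
    if log2_transform:
        df = np.log2(df + 1.0)
    return ExpressionMatrix(df)


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    expr.data.to_csv(path, sep="\t", index_label="gene_id")


def read_clinical(
    path: str | Path, time_col: str = "time", event_col: str = "event"
) -> ClinicalTable:
    """Load a per-sample clinical TSV, excluding unusable survival records.

    Rows with missing event status, missing time, or time <= 0 are dropped
    and the count logged — mirroring the usual cohort curation step where
    patients with no follow-up (or zero survival) are excluded.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    for col in (time_col, event_col):
        if col not in df.columns:
            raise ValueError(f"column '{col}' not found in {path}")
    df = df.rename(columns={time_col: "time", event_col: "event"})
    time = pd.to_numeric(df["time"], errors="coerce")
    event = pd.to_numeric(df["event"], errors="coerce")
    ok = time.notna() & (time > 0) & event.isin([0, 1])
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.info("excluded %d samples lacking usable survival data from %s",
                    n_dropped, path)
    df = df.loc[ok].copy()
    df["time"] = time[ok]
    df["event"] = event[ok].astype(int)
    table = ClinicalTable(df)
    table.n_excluded = n_dropped  # type: ignore[attr-defined]
    return table


def write_clinical(clin: ClinicalTable, path: str | Path) -> None:
    clin.data.to_csv(path, sep="\t", index_label="sample_id")


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file: per line a set name, a description, then members."""
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line has {len(fields)} fields, needs >=3"
                )
            name, desc, *members = fields
            members = [m for m in members if m]
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate gene set name '{name}'")
            if not members:
                raise ValueError(f"{path}:{lineno}: gene set '{name}' has no members")
            sets[name] = members
            descriptions[name] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gmt(gsc: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, members in gsc.sets.items():
            desc = gsc.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *members]) + "\n")


def write_model(model: SignatureModel, path: str | Path) -> None:
    payload = {
        "schema_version": MODEL_SCHEMA_VERSION,
        "pairs": [list(p) for p in model.pairs],
        "coefficients": model.coefficients,
        "auroc_horizon": model.auroc_horizon,
        "cutoff": model.cutoff,
        "provenance": model.provenance,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_model(path: str | Path) -> SignatureModel:
    with open(path) as fh:
        try:
            payload = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ValueError(f"cannot parse model file {path}: {exc}") from exc
    required = ("schema_version", "pairs", "coefficients", "auroc_horizon", "cutoff")
    missing = [k for k in required if k not in payload]
    if missing:
        raise ValueError(f"model file {path} lacks required fields: {missing}")
    if payload["schema_version"] != MODEL_SCHEMA_VERSION:
        raise ValueError(
            f"unsupported model schema version {payload['schema_version']}"
        )
    return SignatureModel(
        pairs=[tuple(p) for p in payload["pairs"]],
        coefficients=list(payload["coefficients"]),
        auroc_horizon=float(payload["auroc_horizon"]),
        cutoff=float(payload["cutoff"]),
        provenance=payload.get("provenance", {}),
    )
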