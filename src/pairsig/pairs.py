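"""Within-sample rank-pair scoring.

The core construction: for a pair of genes (a, b) and a sample s, the
indicator is 1 iff expr[a, s] > expr[b, s], else 0 (ties score 0).  Because
only the within-sample ordering of the two genes matters, the indicator is
invariant under any strictly increasing per-sample transform of expression
— which is what makes pair signatures portable across platforms and batches
without normalisation.

Pairs are stored in a canonical orientation (gene_a < gene_b
lexicographically); the opposite orientation carries no extra information
(its indicator is the complement, up to ties).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, GeneSetCollection

logger = logging.getLogger(__name__)

__all__ = [
    "PairDefinition",
    "PairMatrix",
    "extract_metabolic_genes",
    "build_pair_matrix",
    "filter_invariant_pairs",
    "apply_pairs",
    "write_pairs",
    "read_pairs",
]


class PairDefinition(NamedTuple):
    """An ordered gene pair in canonical orientation (gene_a < gene_b)."""

    gene_a: str
    gene_b: str

    @classmethod
    def canonical(cls, gene_a: str, gene_b: str) -> "PairDefinition":
        if gene_a == gene_b:
            raise ValueError(f"pair with identical genes: {gene_a}")
        return cls(gene_a, gene_b) if gene_a < gene_b else cls(gene_b, gene_a)

    @property
    def label(self) -> str:
        return f"{self.gene_a}|{self.gene_b}"


@dataclass
class PairMatrix:
    """Binary pair-by-sample indicator matrix.

    ``values[i, j]`` is 1 iff gene_a of pair i exceeds gene_b in sample j.
    """

    pairs: list[PairDefinition]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.uint8)
        if self.values.shape != (len(self.pairs), len(self.sample_ids)):
            raise ValueError(
                f"value shape {self.values.shape} inconsistent with "
                f"{len(self.pairs)} pairs x {len(self.sample_ids)} samples"
            )
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("pair matrix values must be 0/1")

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values,
            index=[p.label for p in self.pairs],
            columns=self.sample_ids,
        )

    def subset_pairs(self, pairs: Sequence[PairDefinition]) -> "PairMatrix":
        index = {p: i for i, p in enumerate(self.pairs)}
        missing = [p.label for p in pairs if p not in index]
        if missing:
            raise KeyError(f"pairs absent from matrix: {missing}")
        rows = [index[p] for p in pairs]
        return PairMatrix(list(pairs), list(self.sample_ids), self.values[rows])

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="pair")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PairMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        pairs = []
        for label in df.index:
            a, sep, b = str(label).partition("|")
            if not sep or not b:
                raise ValueError(f"malformed pair label '{label}' in {path}")
            pairs.append(PairDefinition(a, b))
        return cls(pairs, [str(c) for c in df.columns], df.to_numpy())


def extract_metabolic_genes(
    gsc: GeneSetCollection,
    cohorts: Sequence[ExpressionMatrix],
    name_pattern: str = "METABOLISM",
) -> list[str]:
    """Union the members of pathway sets matching ``name_pattern``, then keep
    only genes measured in every cohort.

    The pattern is a case-insensitive substring match against set names
    (e.g. the default picks every ``*_METABOLISM`` KEGG pathway).  Returns
    a sorted, deduplicated gene list.
    """
    if not cohorts:
        raise ValueError("need at least one cohort")
    pat = name_pattern.upper()
    matched = [name for name in gsc.names() if pat in name.upper()]
    if not matched:
        raise ValueError(f"no gene set name contains pattern '{name_pattern}'")
    union: set[str] = set()
    for name in matched:
        union.update(gsc[name])
    present = union.intersection(*(set(c.gene_ids) for c in cohorts))
    if not present:
        raise ValueError(
            f"no gene from the {len(matched)} matched sets is present in all "
            f"{len(cohorts)} cohorts"
        )
    logger.info(
        "extracted %d genes from %d matching sets (%d before cohort intersection)",
        len(present), len(matched), len(union),
    )
    return sorted(present)


def _pair_index(genes: Sequence[str]) -> tuple[list[str], np.ndarray, np.ndarray]:
    ordered = sorted(genes)
    iu, ju = np.triu_indices(len(ordered), k=1)
    return ordered, iu, ju


def build_pair_matrix(expr: ExpressionMatrix, genes: Sequence[str]) -> PairMatrix:
    """Build the full C(n, 2) indicator matrix over ``genes`` in ``expr``."""
    if len(set(genes)) < 2:
        raise ValueError("need at least 2 distinct genes to form pairs")
    ordered, iu, ju = _pair_index(genes)
    sub = expr.subset_genes(ordered)  # raises naming any missing gene
    arr = sub.values
    values = (arr[iu] > arr[ju]).astype(np.uint8)
    pairs = [PairDefinition(ordered[i], ordered[j]) for i, j in zip(iu, ju)]
    return PairMatrix(pairs, sub.sample_ids, values)


def filter_invariant_pairs(
    matrices: Mapping[str, PairMatrix], threshold: float = 0.80
) -> tuple[list[PairDefinition], list[PairDefinition]]:
    """Drop pairs that are nearly constant in any cohort.

    A pair is excluded iff in ANY cohort its majority class (all-1 or all-0)
    covers strictly more than ``threshold`` of the samples; a pair sitting
    exactly at the threshold is kept.  Returns ``(kept, excluded)`` in the
    shared canonical order.
    """
    if not matrices:
        raise ValueError("need at least one cohort pair matrix")
    mats = list(matrices.values())
    ref = mats[0].pairs
    for name, pm in matrices.items():
        if pm.pairs != ref:
            raise ValueError(f"cohort '{name}' has a mismatched pair list")
    excluded_mask = np.zeros(len(ref), dtype=bool)
    for pm in mats:
        frac_ones = pm.values.mean(axis=1)
        majority = np.maximum(frac_ones, 1.0 - frac_ones)
        excluded_mask |= majority > threshold
    kept = [p for p, ex in zip(ref, excluded_mask) if not ex]
    excluded = [p for p, ex in zip(ref, excluded_mask) if ex]
    logger.info("invariance filter: %d kept, %d excluded of %d pairs",
                len(kept), len(excluded), len(ref))
    return kept, excluded


def apply_pairs(
    expr: ExpressionMatrix, pairs: Sequence[PairDefinition]
) -> PairMatrix:
    """Project a cohort into an existing pair space (e.g. a validation set)."""
    needed = sorted({g for p in pairs for g in p})
    missing = [g for g in needed if g not in expr.data.index]
    if missing:
        raise KeyError(f"genes absent from expression matrix: {missing}")
    data = expr.data.loc[needed]
    loc = {g: i for i, g in enumerate(needed)}
    arr = data.to_numpy()
    ia = np.array([loc[p.gene_a] for p in pairs], dtype=int)
    ib = np.array([loc[p.gene_b] for p in pairs], dtype=int)
    values = (arr[ia] > arr[ib]).astype(np.uint8)
    return PairMatrix(list(pairs), [str(c) for c in data.columns], values)


def write_pairs(pairs: Sequence[PairDefinition], path: str | Path) -> None:
    pd.DataFrame(pairs, columns=["gene_a", "gene_b"]).to_csv(
        path, sep="\t", index=False
    )


def read_pairs(path: str | Path) -> list[PairDefinition]:
    df = pd.read_csv(path, sep="\t")
    for col in ("gene_a", "gene_b"):
        if col not in df.columns:
            raise ValueError(f"pair file {path} lacks column '{col}'")
    return [PairDefinition(a, b) for a, b in zip(df["gene_a"], df["gene_b"])]
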