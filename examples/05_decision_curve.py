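"""Decision-curve analysis of a risk score.

Simulates survival driven by a score, converts the score to a predicted
event probability at a horizon via a Cox fit, and prints the net benefit
of acting on the prediction against the treat-all / treat-none policies.
"""

import numpy as np

from pairsig import decision_curve
from pairsig.reporting import risk_to_event_probability

from pairsig.io import ClinicalTable
import pandas as pd

rng = np.random.default_rng(13)
n = 300
score = rng.normal(size=n)
event_time = rng.exponential(2.0 * np.exp(-1.2 * score)) + 1e-6
censor_time = rng.uniform(0, 8.0, size=n)
time = np.minimum(event_time, censor_time)
event = (event_time <= censor_time).astype(int)
clin = ClinicalTable(pd.DataFrame(
    {"time": time, "event": event}, index=[f"s{i}" for i in range(n)]
))

horizon = 2.0
prob = risk_to_event_probability(score, clin, horizon)
outcome = ((time <= horizon) & (event == 1)).astype(int)

curve = decision_curve(prob, outcome, np.round(np.arange(0.1, 0.8, 0.1), 2))
print(curve.to_frame().round(4).to_string(index=False))
# Net benefit above BOTH reference lines at a threshold pt means acting on
# the model at that risk tolerance beats treating everyone or no one;
# pt is the odds at which a clinician weighs false positives.
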