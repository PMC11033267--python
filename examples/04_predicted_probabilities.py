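"""Predicted-probability scenarios, age trends, and a sex contrast.

Fits the fixed-effects variant (age, sex, age x sex per role, plus the
same-household flag) to a small synthetic study whose generator makes the
first behavior more likely for older initiators, then (1) sweeps initiator
age and labels each behavior's trend, and (2) contrasts boy- vs
girl-initiated predictions at the mean age.
"""

import numpy as np

from dyadmnl import (
    McmcConfig,
    ModelSpec,
    PredictionScenario,
    build_design,
    contrast,
    fit,
    label_age_trend,
    predict_probabilities,
)
from dyadmnl.synthetic import SimulationConfig, draw_truth, simulate_community, simulate_observations

cfg = SimulationConfig(n_children=30, n_households=12, n_categories=4, n_events=1500, seed=21)
roster = simulate_community(cfg)
truth = draw_truth(
    cfg,
    {
        "alpha": [0.4, -0.2, 0.1],
        "beta_I": [[0.9, 0.6, 0.0], [-0.7, 0.0, 0.0], [0.0, -0.5, 0.0]],
        "scale_I": [0.2] * 3,
        "scale_R": [0.2] * 3,
    },
)
events, _ = simulate_observations(roster, truth, cfg)
data = build_design(events, roster, cfg.taxonomy())
samples = fit(ModelSpec(variant="iF", K=4), data, McmcConfig.desk(seed=5, iterations=1000))

ages = tuple(np.arange(0.5, 12.5, 0.5))
curve = predict_probabilities(samples, PredictionScenario(varying="initiator_age", grid=ages))
print("age trends (initiator age, female/female, different household):")
for label, trend in label_age_trend(curve).items():
    extra = f" peak {trend.peak_interval}" if trend.peak_interval else ""
    print(f"  {label:22s} {trend.kind}{extra}")

boys = PredictionScenario(initiator_sex=1.0)
girls = PredictionScenario(initiator_sex=0.0)
print("\nboy-minus-girl initiator contrast at mean ages:")
print(contrast(samples, boys, girls)[["behavior", "difference", "lower", "upper", "significant"]]
      .round(3).to_string(index=False))
print("-> a positive generating age coefficient shows up as an increasing")
print("   trend; the sex coefficient drives the significant contrast rows.")
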