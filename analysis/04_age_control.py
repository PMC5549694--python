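#!/usr/bin/env python
"""Tissue-age control: is months-since-extraction predictable from spectra?

Refits the same pipeline with continuous y = storage age (1-80 months) in
two regimes: (a) the default generator, whose ages are independent of every
spectral feature — the model should have no predictive ability; (b) a
positive-control generator with an age-linked resonance injected at 2.7 ppm
— the same pipeline should then predict age well, proving the null result in
(a) is not a pipeline blind spot. Reduced-resolution cohorts (4096 points)
keep the multi-seed null fast. Writes results/age_control/summary.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from lymphospec import synthetic_data as sd
from lymphospec import workflow as wf
from lymphospec.spectra_io import AcquisitionParams

OUT = Path(__file__).resolve().parents[1] / "results" / "age_control"
ACQ = AcquisitionParams(n_points=4096)
N_NULL_SEEDS = 20


def run_one(cfg):
    cohort = sd.generate_cohort(cfg)
    design = wf.StudyDesign(cohort.train_ids, cohort.test_ids)
    return wf.run_age_control(cohort.spectra, cohort.labels, design)


def main() -> None:
    rows = []
    for seed in range(N_NULL_SEEDS):
        res = run_one(sd.SyntheticConfig(seed=seed, acquisition=ACQ))
        rows.append({"regime": "null", "seed": seed, "q2y": res["q2y"],
                     "test_r": res["test_correlation"]})
    pos = run_one(sd.SyntheticConfig(seed=5, acquisition=ACQ,
                                     age_effect_amplitude=0.3))
    rows.append({"regime": "positive_control", "seed": 5, "q2y": pos["q2y"],
                 "test_r": pos["test_correlation"]})

    df = pd.DataFrame(rows)
    OUT.mkdir(parents=True, exist_ok=True)
    df.to_csv(OUT / "summary.csv", index=False)

    null = df[df.regime == "null"]
    print(f"age model on independent ages ({N_NULL_SEEDS} seeds): "
          f"mean Q2Y = {null.q2y.mean():.3f}, "
          f"mean |r(pred, true)| on test = {null.test_r.abs().mean():.3f}")
    print("  -> no predictive ability: storage age cannot explain the "
          "benign/malignant separation")
    print(f"positive control (age-linked 2.7 ppm resonance): "
          f"Q2Y = {pos['q2y']:.3f}, test r = {pos['test_correlation']:.3f}")
    print("  -> the pipeline does detect an age effect when one exists")
    print(f"wrote {OUT/'summary.csv'}")


if __name__ == "__main__":
    main()
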