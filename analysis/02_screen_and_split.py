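#!/usr/bin/env python
"""Preprocess the cohort: exclusion, 70/30 split, imputation, screening.

Reads ``results/cohort.csv`` (run 01 first), drops records that fail
the completeness policy, splits 70/30 (training medians imputed into
both splits), and screens each predictor against the ventilation
outcome (ANOVA for numerics, chi-square for sex/age). Writes the splits
and the screen table under ``results/``.
"""

import json
from pathlib import Path

from edvent.cohort import Cohort, exclude_incomplete
from edvent.pipeline import substream_seed
from edvent.preprocessing import median_impute, screen_features, train_test_split

MASTER_SEED = 1
OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    cohort = Cohort.from_csv(OUT / "cohort.csv")
    cohort, n_excluded = exclude_incomplete(cohort)
    print(f"exclusion: {n_excluded} records dropped, {len(cohort)} analysed")

    split = train_test_split(cohort, 0.7, seed=substream_seed(MASTER_SEED, "split"))
    train = median_impute(split.train)
    test = median_impute(split.train, split.test)
    print(f"split: training {len(train)}, test {len(test)} (expected 734 / 315)")
    train.to_csv(OUT / "train.csv")
    test.to_csv(OUT / "test.csv")
    with open(OUT / "split_manifest.json", "w") as fh:
        json.dump({"fraction": 0.7, "seed": MASTER_SEED,
                   "train": len(train), "test": len(test)}, fh, indent=2)

    screen = screen_features(cohort, alpha=0.05)
    screen.to_csv(OUT / "feature_screen.csv")
    sig = screen.significant_features()
    print(f"screen: {len(sig)}/{len(screen.table)} features significant at alpha=0.05")
    print("significant:", ", ".join(sig))


if __name__ == "__main__":
    main()
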