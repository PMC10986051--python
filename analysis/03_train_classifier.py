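#!/usr/bin/env python
"""Train and evaluate the ventilation-need random forest.

Tunes the tree count ({100..500}, 3 variables per split, 10-fold CV by
mean AUC) on the training split, then reports the full test-set
battery: sensitivity/specificity/PPV/NPV with exact 95% CIs, ROC AUC
with a DeLong interval, McNemar's exact test, and the Gini importance
(MDGC) ranking. Run 01 and 02 first.
"""

import json
from pathlib import Path

from edvent.classifier import (
    ClassifierConfig,
    compute_metrics,
    confusion_at_threshold,
    mcnemar_test,
    mdgc_ranking,
    predict_prob,
    roc_auc_ci,
    train_tune,
)
from edvent.cohort import Cohort
from edvent.pipeline import substream_seed

MASTER_SEED = 1
OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    train = Cohort.from_csv(OUT / "train.csv")
    test = Cohort.from_csv(OUT / "test.csv")

    model = train_tune(train, ClassifierConfig(seed=substream_seed(MASTER_SEED, "model")))
    print(f"selected forest size: {model.n_trees} trees")
    print(model.cv_results.to_string(index=False))

    probs = predict_prob(model, test)
    outcomes = test.df["outcome"].to_numpy(int)
    metrics = compute_metrics(confusion_at_threshold(probs, outcomes, 0.5))
    metrics.auc = roc_auc_ci(probs, outcomes)
    metrics.mcnemar_p = mcnemar_test((probs >= 0.5).astype(int), outcomes).p_value

    for name in ("sensitivity", "specificity", "ppv", "npv", "auc"):
        est, lo, hi = getattr(metrics, name)
        print(f"{name:12s} {est * 100:6.2f}%  95% CI [{lo * 100:.2f}, {hi * 100:.2f}]")
    print(f"McNemar p = {metrics.mcnemar_p:.4f}")

    with open(OUT / "metrics.json", "w") as fh:
        json.dump(metrics.to_dict(), fh, indent=2)
    ranking = mdgc_ranking(model)
    ranking.to_csv(OUT / "importances.csv", index=False)
    print("top importances (MDGC):")
    print(ranking.head(5).to_string(index=False))


if __name__ == "__main__":
    main()
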