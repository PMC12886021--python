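#!/usr/bin/env python
"""Evaluate the trained classifier on the hold-out set.

Scores the hold-out samples, reports AUC, sensitivity/specificity with
Wilson intervals, early- vs late-stage sensitivity, PPV/NPV at 1% assumed
prevalence, the CA19-9 comparison at the 37 U/mL cutoff, the Bayes-oracle
ceiling, and subgroup-bias association tests; writes a JSON report.
"""

import argparse
import json
from pathlib import Path

import pandas as pd
from sklearn.metrics import roc_auc_score

from uroevmir import evaluate as ev
from uroevmir.classify import ClassifierBundle
from uroevmir.pipeline import evaluate_holdout, holdout_features
from uroevmir.simulate import CohortDesign, oracle_scores


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1,
                    help="seed of the cohort written by 01_simulate_cohort.py")
    ap.add_argument("--prevalence", type=float, default=0.01)
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()

    counts = pd.read_csv(args.outdir / "counts.tsv", sep="\t", index_col=0)
    meta = pd.read_csv(args.outdir / "meta.tsv", sep="\t")
    meta = meta.set_index("sample_id", drop=False)
    meta.index.name = None
    bundle = ClassifierBundle.load(args.outdir / "classifier_bundle.json")

    report = evaluate_holdout(counts, meta, bundle, args.prevalence)

    ids = bundle.split["holdout_ids"]
    X, y = holdout_features(counts[ids], meta.loc[ids], bundle)
    scores, _ = bundle.predict(X)

    # CA19-9 comparison on the same hold-out samples
    sub = meta.loc[ids]
    sens, spec, n_used = ev.ca199_classify(sub["ca19_9"], y)
    report["ca19_9"] = {"sensitivity": sens, "specificity": spec,
                        "n_used": n_used}

    # Bayes-oracle ceiling under the generating design
    design = CohortDesign(seed=args.seed)
    osc = oracle_scores(design, counts)
    report["oracle_auc_holdout"] = float(roc_auc_score(y, osc[ids]))

    # subgroup bias of the prediction scores
    assoc = {}
    for cov in ("age", "sex"):
        assoc[cov] = ev.subgroup_association(scores, sub[cov])
    assoc["ca19_9"] = ev.subgroup_association(scores, sub["ca19_9"])
    report["subgroup_association"] = assoc

    out = args.outdir / "holdout_report.json"
    out.write_text(json.dumps(report, indent=2, default=float))
    print(f"hold-out AUC {report['auc']:.3f} "
          f"(oracle ceiling {report['oracle_auc_holdout']:.3f})")
    print(f"sensitivity {report['sensitivity']:.3f} "
          f"CI {tuple(round(v, 3) for v in report['sensitivity_ci'])}, "
          f"specificity {report['specificity']:.3f} "
          f"CI {tuple(round(v, 3) for v in report['specificity_ci'])}")
    early = report["by_stage"]["early"]
    late = report["by_stage"]["late"]
    print(f"early-stage sensitivity {early['sensitivity']:.3f} "
          f"({early['n_detected']}/{early['n']}), late-stage "
          f"{late['sensitivity']:.3f} ({late['n_detected']}/{late['n']})")
    print(f"PPV {report['ppv']:.3f} / NPV {report['npv']:.3f} at "
          f"{args.prevalence:.0%} prevalence")
    print(f"CA19-9: sensitivity {sens:.3f}, specificity {spec:.3f} "
          f"(n={n_used})")
    print(f"report written to {out}")


if __name__ == "__main__":
    main()
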