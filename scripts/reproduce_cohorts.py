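"""End-to-end cohort evaluation: the full pipeline on user-supplied data.

Given an expression matrix and response labels for a clinical cohort (for
example a GEO series matrix exported to TSV plus its responder annotation),
this script runs the complete protocol:

1. quantile normalization of the sample rows (optional, for raw intensities);
2. class equalization by seeded subsampling of the larger class;
3. marker-gene selection — either the top-30 single-gene AUC list or the
   leave-one-out "core" intersection;
4. leave-one-out evaluation of the trimming classifier (both confidence
   settings p = 0.95 and p = 0.90) next to the classical-SVM baseline;
5. a metrics table (AUC, FDR, Sn, Sp, ACC, MCC, tau) per classifier.

Cohort downloads are out of scope for the package; point ``--matrix`` and
``--labels`` at local files.  Expect multi-hour runtimes on full-size
cohorts (hundreds of samples); the nested leave-one-out sweep is quadratic
in cohort size.

Usage::

    python scripts/reproduce_cohorts.py --matrix cohort.tsv --labels labels.tsv \
        --features core --kernel linear --C 1.0 --out results/cohort/
"""

import argparse
import pathlib

from flowps import (
    ClassifierConfig,
    classical_svm_loo,
    core_genes,
    equalize_classes,
    loo_evaluate,
    quantile_normalize_dataset,
    read_expression_dataset,
    top_n_genes,
    write_metrics,
    write_predictions,
)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--matrix", required=True)
    ap.add_argument("--labels", required=True)
    ap.add_argument("--orientation", default="samples_by_genes",
                    choices=["samples_by_genes", "genes_by_samples"])
    ap.add_argument("--quantile-normalize", action="store_true")
    ap.add_argument("--features", default="top30", choices=["top30", "core", "all"])
    ap.add_argument("--n-top", type=int, default=30)
    ap.add_argument("--kernel", default="linear", choices=["linear", "poly"])
    ap.add_argument("--C", type=float, default=1.0)
    ap.add_argument("--k-min", type=int, default=20)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", type=pathlib.Path, required=True)
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    ds = read_expression_dataset(args.matrix, args.labels, args.orientation)
    if args.quantile_normalize:
        ds = quantile_normalize_dataset(ds)
    ds = equalize_classes(ds, seed=args.seed)
    n_top = min(args.n_top, ds.n_features)
    if args.features == "top30":
        ds = ds.subset_genes(top_n_genes(ds, n_top).gene_ids)
    elif args.features == "core":
        core = sorted(core_genes(ds, n_top))
        if not core:
            raise SystemExit("core marker set is empty for this cohort")
        ds = ds.subset_genes(core)
    print(f"evaluating {ds.n_samples} samples x {ds.n_features} genes")

    reports = {}
    svm_cfg = ClassifierConfig(kernel=args.kernel, C=args.C, seed=args.seed)
    scores, reports["svm"] = classical_svm_loo(ds, svm_cfg)
    for p in (0.95, 0.90):
        cfg = ClassifierConfig(kernel=args.kernel, C=args.C, p=p,
                               k_min=args.k_min, seed=args.seed)
        records, reports[f"flowps_p{p:.2f}"] = loo_evaluate(ds, cfg)
        write_predictions(records, args.out / f"predictions_flowps_p{p:.2f}.tsv")
    write_metrics(reports, args.out / "metrics.tsv")
    for name, rep in reports.items():
        print(f"{name}: AUC={rep.auc:.3f} FDR={rep.fdr:.3f} ACC={rep.acc:.3f} "
              f"MCC={rep.mcc:.3f}")


if __name__ == "__main__":
    main()
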