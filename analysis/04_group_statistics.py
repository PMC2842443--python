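"""Group statistics on the precomputed surface maps.

Loads the map and ROI tables written by 03_surface_maps.py and runs the
full battery: vertex-wise GLM with permutation omnibus (deformation maps
adjusted for intracranial volume, FA maps diagnosis-only), PCA + t-test
component selection + leave-one-out LDA classification of both map types
and of the ROI baselines, and the canonical-score correlation with MMSE.

Outputs (under --results):
    report.json             every statistic of the battery
    table_classifiers.csv   accuracy / sensitivity / specificity / F per analysis
"""

import argparse
import json
import os

import numpy as np
import pandas as pd

from tractsurf.stats_pipeline import (DesignMatrix, bonferroni_threshold,
                                      canonical_scores, classify_maps,
                                      lda_loocv, pca_reduce, permutation_omnibus,
                                      select_pcs, vertexwise_glm)


def _load(results: str, name: str, table: pd.DataFrame) -> np.ndarray:
    df = pd.read_csv(os.path.join(results, f"{name}.csv"))
    df = table[["subject_id"]].merge(df, on="subject_id", validate="one_to_one")
    return df.drop(columns="subject_id").to_numpy(float)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--results", type=str, default="results")
    ap.add_argument("--n-perm", type=int, default=10000)
    ap.add_argument("--alpha", type=float, default=0.05)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--mode", choices=["paper", "nested"], default="paper")
    args = ap.parse_args()

    table = pd.read_csv(os.path.join(args.results, "cohort.csv"))
    y = table["diagnosis"].to_numpy(int)
    icv = table["icv_mm3"].to_numpy(float)
    mmse = table["mmse"].to_numpy(float)
    lj = _load(args.results, "deformation_maps", table)
    fa = _load(args.results, "fa_maps", table)
    volumes = _load(args.results, "roi_volumes", table)
    meanfa = _load(args.results, "roi_meanfa", table)

    design_shape = DesignMatrix(y, covariates=icv[:, None])
    design_fa = DesignMatrix(y)
    perm_shape = permutation_omnibus(lj, design_shape, alpha=args.alpha,
                                     n_perm=args.n_perm, seed=args.seed)
    perm_fa = permutation_omnibus(fa, design_fa, alpha=args.alpha,
                                  n_perm=args.n_perm, seed=args.seed + 1)
    print(f"deformation omnibus p = {perm_shape.overall_p:.4f} "
          f"({perm_shape.observed_count} suprathreshold vertices)")
    print(f"FA omnibus p = {perm_fa.overall_p:.4f} "
          f"({perm_fa.observed_count} suprathreshold vertices)")

    rows, report = [], {}
    for name, X in (("deformation_maps", lj), ("fa_maps", fa)):
        clf, sel = classify_maps(X, y, alpha=args.alpha, mode=args.mode)
        rows.append({"analysis": name, "accuracy_pct": clf.accuracy_pct,
                     "sensitivity_pct": clf.sensitivity_pct,
                     "specificity_pct": clf.specificity_pct,
                     "f_score": clf.f_score})
        report[name] = {"selected_pcs_1based": [int(i) + 1 for i in sel],
                        **rows[-1]}
    for name, X in (("roi_volumes", volumes), ("roi_meanfa", meanfa)):
        glm = vertexwise_glm(X, design_shape if name == "roi_volumes" else design_fa)
        keep = np.flatnonzero(glm.p < args.alpha)
        if keep.size == 0:
            keep = np.array([int(np.argmin(glm.p))])
        clf = lda_loocv(X[:, keep], y)
        rows.append({"analysis": name, "accuracy_pct": clf.accuracy_pct,
                     "sensitivity_pct": clf.sensitivity_pct,
                     "specificity_pct": clf.specificity_pct,
                     "f_score": clf.f_score})
        report[name] = {"tracts_used_1based": [int(i) + 1 for i in keep],
                        **rows[-1]}

    for name, X in (("deformation_maps", lj), ("fa_maps", fa)):
        pca = pca_reduce(X)
        sel, pv = select_pcs(pca.scores, y, alpha=args.alpha)
        if sel.size == 0:
            sel = np.array([int(np.argmin(pv))])
        canon = canonical_scores(pca.scores[:, sel], y, mmse=mmse)
        report[f"{name}_canonical_mmse"] = {"pearson_r": round(canon.pearson_r, 4),
                                            "p": round(canon.p, 4)}
        print(f"{name}: canonical score vs MMSE r = {canon.pearson_r:.4f} "
              f"(p = {canon.p:.4f})")

    report["deformation_permutation_p"] = perm_shape.overall_p
    report["fa_permutation_p"] = perm_fa.overall_p
    report["bonferroni_threshold_3_tracts"] = round(
        bonferroni_threshold(args.alpha, 3), 4)

    pd.DataFrame(rows).to_csv(os.path.join(args.results,
                                           "table_classifiers.csv"), index=False)
    with open(os.path.join(args.results, "report.json"), "w") as fh:
        json.dump(report, fh, indent=2)
    print(pd.DataFrame(rows).to_string(index=False))
    print(f"wrote report.json and table_classifiers.csv to {args.results}/")


if __name__ == "__main__":
    main()
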