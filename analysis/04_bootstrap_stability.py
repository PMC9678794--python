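"""Bootstrap stability selection and tier classification.

Resamples matched pairs with replacement, refits every protein's
adjusted logistic model per resample, re-applies Benjamini-Hochberg FDR
within each resample, and ranks proteins by the proportion of resamples
in which they stay significant.  Tiers follow the published semantics:
>=80% selected -> major mechanistic importance; 50-80% -> potential
significance.

The default here is a scaled run of B = 200 resamples (the full design
uses B = 5000; pass a different count as the first argument).

Reads results/study/; writes results/stability.csv.
"""

import sys
import time

from proteohf import load_study, filter_by_lod, StabilityConfig, bootstrap_selection


def main(n_bootstrap: int = 200, seed: int = 20260924) -> None:
    study = load_study(
        "results/study/subjects.csv",
        "results/study/protein_matrix.csv",
        "results/study/assay_meta.csv",
    )
    filtered, _ = filter_by_lod(study.matrix, study.assay_meta)

    config = StabilityConfig(n_bootstrap=n_bootstrap, seed=seed)
    t0 = time.time()
    stab = bootstrap_selection(study.subjects, filtered, config)
    stab.to_csv("results/stability.csv", index=False)
    print(f"B = {n_bootstrap} bootstrap resamples over {filtered.shape[1]} "
          f"proteins in {time.time() - t0:.0f} s")

    counts = stab["tier"].value_counts()
    print(f"tiers: {counts.get('major', 0)} major, "
          f"{counts.get('potential', 0)} potential, "
          f"{counts.get('none', 0)} unselected")
    top = stab.sort_values("selection_proportion", ascending=False).head(12)
    print("\nmost stable proteins (selection proportion):")
    for r in top.itertuples():
        print(f"  {r.assay}: {r.selection_proportion:.1%} [{r.tier}]")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 200,
         int(sys.argv[2]) if len(sys.argv) > 2 else 20260924)
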