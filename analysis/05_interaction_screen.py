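"""Screen stable proteins for interaction with the obesity intervention.

For each protein in the major/potential tiers, tests whether its
association with incident HF differs between the bariatric-surgery and
usual-care strata (product term in the pooled adjusted model, screening
alpha 0.10) and reports stratum-specific odds ratios from stratified
refits.  Also writes the Spearman correlation matrix of the major-tier
proteins.

Reads results/study/ and results/stability.csv; writes
results/interaction.csv and results/correlation_major.csv.
"""

import pandas as pd

from proteohf import load_study, filter_by_lod, interaction_screen, spearman_matrix


def main(alpha: float = 0.10) -> None:
    study = load_study(
        "results/study/subjects.csv",
        "results/study/protein_matrix.csv",
        "results/study/assay_meta.csv",
    )
    filtered, _ = filter_by_lod(study.matrix, study.assay_meta)
    stab = pd.read_csv("results/stability.csv")

    screened = stab.loc[stab["tier"] != "none", "assay"].tolist()
    inter = interaction_screen(study.subjects, filtered, screened, alpha)
    inter.to_csv("results/interaction.csv", index=False)

    flagged = inter[inter["flagged"]]
    print(f"screened {len(inter)} stable proteins at interaction alpha {alpha}; "
          f"{len(flagged)} flagged")
    for r in flagged.itertuples():
        print(f"  {r.assay}: sOR {r.or_no_surgery:.2f} without surgery vs "
              f"{r.or_surgery:.2f} with surgery, p_int = {r.p_interaction:.3f}")

    truth = pd.read_csv("results/study/truth.csv")
    planted = set(truth.loc[truth["interaction_log_or"] != 0, "assay"])
    print(f"planted surgery-dependent effects among flagged: "
          f"{len(set(flagged['assay']) & planted)}/{len(planted)}")

    major = stab.loc[stab["tier"] == "major", "assay"].tolist()
    rho = spearman_matrix(filtered[major])
    rho.index.name = "assay"
    rho.to_csv("results/correlation_major.csv")
    print(f"wrote Spearman correlations of the {len(major)} major-tier proteins")


if __name__ == "__main__":
    main()
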