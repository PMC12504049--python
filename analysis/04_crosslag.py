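"""Directional cross-lagged analysis: does baseline WMH predict atrophy?

Fits every WMH <-> subcortical pair in both directions on the longitudinal
GRN carriers (rate of change of the z-scored response on the predictor's
baseline plus age, sex, education, log NfL, and the response's own
baseline), applies one Benjamini-Hochberg family over all 48 tests, and
prints the significant directed associations.
"""

from pathlib import Path

import pandas as pd

from ftdprog.crosslag import association_matrix, t_statistic_matrix

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    cohort = pd.read_csv(OUT / "cohort.csv")
    multi = cohort.groupby("subject_id")["visit_time"].nunique()
    rows = cohort[cohort.subject_id.isin(multi[multi >= 2].index)
                  & (cohort.genotype == "GRN")]
    print(f"longitudinal GRN subjects: {rows.subject_id.nunique()}")

    results = association_matrix(rows)
    results.to_csv(OUT / "crosslag_results.csv", index=False)
    t_statistic_matrix(results).to_csv(OUT / "crosslag_t_matrix.csv")

    sig = results[results.significant]
    print(f"\n{len(sig)} of {len(results)} directed pairs significant at "
          "FDR < 0.05:")
    print(sig[["direction", "predictor", "response", "coefficient", "t",
               "p_raw", "p_fdr"]].to_string(index=False))
    n_rev = (sig.direction == "reverse").sum()
    print(f"\nreverse-direction (subcortical -> WMH) significant pairs: {n_rev}")


if __name__ == "__main__":
    main()
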