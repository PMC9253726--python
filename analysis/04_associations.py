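"""Association statistics across the panel: FRP, first LL peak, and CDL.

Merges the rhythm and flowering phenotypes, runs Pearson correlation tests
and Deming regressions for the three pairings (excluding strains flagged by
the rhythm filter from FRP-involving analyses), and compares phenotypes
across populations with pairwise Wilcoxon tests (Holm-adjusted) summarized
as compact letter displays.
"""

import sys
from pathlib import Path

import pandas as pd

from lemnaclock.io import write_table
from lemnaclock.stats import pairwise_wilcoxon, panel_association

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    results = ROOT / "results"
    strains = pd.read_csv(results / "strain_rhythms.csv", comment="#")
    cdl = pd.read_csv(results / "cdl_estimates.csv", comment="#")
    truth = pd.read_csv(results / "panel_ground_truth.csv", comment="#")
    records = (
        strains.merge(cdl[["strain", "cdl_h", "fmax_pct"]], on="strain")
        .merge(truth[["strain_id", "population_id", "latitude_deg"]],
               left_on="strain", right_on="strain_id")
    )
    write_table(records, results / "strain_records.csv")

    report = panel_association(records)
    write_table(report, results / "association_report.csv")
    print("pairwise associations (Deming delta = 1):")
    print(report.round(4).to_string(index=False))

    usable = records[~records["excluded"]]
    letter_rows = []
    for pheno in ["mean_frp_h", "cdl_h"]:
        groups = {pop: g[pheno].to_numpy()
                  for pop, g in usable.groupby("population_id")}
        res = pairwise_wilcoxon(groups, alpha=0.05)
        for pop in res.labels:
            letter_rows.append({"phenotype": pheno, "population": pop,
                                "letters": res.letters[pop],
                                "n": len(groups[pop])})
    letters_df = pd.DataFrame(letter_rows)
    write_table(letters_df, results / "population_letters.csv")
    print("\npopulation comparisons (pairwise Wilcoxon, Holm-adjusted, alpha 0.05):")
    print(letters_df.to_string(index=False))


if __name__ == "__main__":
    sys.exit(main())
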