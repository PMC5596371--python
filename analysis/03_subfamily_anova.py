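#!/usr/bin/env python
"""Step 3 — do asymmetry indices differ among orchid subfamilies?

Runs the one-way ANOVA of each index across subfamilies (excluding the
single-member Vanillioideae, which contributes no within-group variance),
followed by Tukey-Kramer pairwise comparisons with a compact letter
display.  Writes results/03_anova.csv and results/03_tukey_<index>.csv.
"""

from pathlib import Path

import pandas as pd

from karyoasym.compare import one_way_anova, summarize_by_group, tukey_hsd
from karyoasym.pipeline import ANOVA_INDEXES
from karyoasym.table2 import load_karyomorph_table

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    table = load_karyomorph_table()
    OUT.mkdir(exist_ok=True)

    rows = []
    for index_name in ANOVA_INDEXES:
        res = one_way_anova(
            table[index_name], table["subfamily"], min_group_size=2
        )
        rows.append(
            {
                "index": index_name,
                "f_statistic": round(res.f_statistic, 4),
                "p_value": round(res.p_value, 6),
                "df_between": res.df_between,
                "df_within": res.df_within,
                "n_used": res.n_used,
            }
        )
        print(
            f"{index_name}: F({res.df_between},{res.df_within}) = "
            f"{res.f_statistic:.4f}, p = {res.p_value:.4f}, n = {res.n_used}"
        )
        tk = tukey_hsd(table[index_name], table["subfamily"], min_group_size=2)
        tk.pairwise.to_csv(OUT / f"03_tukey_{index_name}.csv", index=False)
        print(f"  letters: {tk.letters}")

    pd.DataFrame(rows).to_csv(OUT / "03_anova.csv", index=False)

    summary_rows = []
    for index_name in ANOVA_INDEXES:
        for gs in summarize_by_group(table[index_name], table["subfamily"]):
            summary_rows.append({"index": index_name, **vars(gs)})
    pd.DataFrame(summary_rows).to_csv(OUT / "03_group_summaries.csv", index=False)


if __name__ == "__main__":
    main()
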