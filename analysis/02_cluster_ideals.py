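#!/usr/bin/env python
"""Step 2 — cluster real taxa together with the six ideal karyotypes.

For each intrachromosomal asymmetry index (TF%, Ask%, Syi, A1, A), the 62
taxa plus the six equal-length ideal karyotypes (arm-ratio ladder A = 1.0
to F = telocentric) are binned into five equal-width categories, compared
by absolute ordinal distance, clustered with size-weighted UPGMA over ten
seeded replicates, and summarized as a strict-majority consensus tree
rooted on the fully symmetric ideal A.

Writes consensus trees (Newick) and per-taxon nearest-ideal assignments to
results/.
"""

from pathlib import Path

import pandas as pd

from karyoasym.cluster import run_cluster_analysis
from karyoasym.pipeline import CLUSTER_INDEXES, RunConfig, values_with_ideals
from karyoasym.table2 import load_karyomorph_table

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    table = load_karyomorph_table().rename(columns={"subfamily": "group"})
    cfg = RunConfig()
    OUT.mkdir(exist_ok=True)

    assignments = []
    for index_name in CLUSTER_INDEXES:
        vals = values_with_ideals(table, index_name, cfg)
        res = run_cluster_analysis(
            vals,
            index_name=index_name,
            n_replicates=cfg.n_replicates,
            n_bins=cfg.n_bins,
            seed=cfg.seed,
        )
        newick = res.consensus.as_string(schema="newick").strip()
        (OUT / f"02_consensus_{index_name}.nwk").write_text(newick + "\n")
        near = res.nearest_ideal.assign(index=index_name)
        assignments.append(near)
        counts = near["nearest_ideal"].value_counts().sort_index()
        print(f"{index_name}: nearest-ideal counts {counts.to_dict()}")

    pd.concat(assignments).to_csv(OUT / "02_nearest_ideal.csv", index=False)

    focus = pd.concat(assignments).set_index(["index", "taxon"])
    for taxon in ("Sarcoglottis grandiflora", "Christensonella pachyphylla"):
        placements = {
            idx: focus.loc[(idx, taxon), "nearest_ideal"]
            for idx in CLUSTER_INDEXES
        }
        print(f"{taxon}: {placements}")


if __name__ == "__main__":
    main()
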