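"""End-to-end analysis: indices, clustering against ideals, group tests.

Ties the stages together the way the full study runs: compute (or load)
per-taxon index values, append the six ideal karyotypes as pseudo-taxa,
run the per-index cluster pipeline, and compare index means across groups
by ANOVA and Tukey.  Deterministic under a fixed configuration; every
output table carries a header comment with the package version and a hash
of the configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__, indices
from .cluster import run_cluster_analysis
from .compare import one_way_anova, summarize_by_group, tukey_hsd
from .ideals import ideal_series
from .model import karyotypes_from_measurements, read_measurements
from .table2 import load_karyomorph_table

__all__ = ["RunConfig", "indices_table", "values_with_ideals", "run_full_analysis"]

CLUSTER_INDEXES = ("tf", "ask", "syi", "a1", "a_watanabe")
ANOVA_INDEXES = ("a2", "ask", "syi", "a1", "a_watanabe")


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one full analysis run."""

    measurements: str | None = None  # per-chromosome CSV; None -> packaged table
    group_column: str = "subfamily"
    cluster_indexes: tuple[str, ...] = CLUSTER_INDEXES
    anova_indexes: tuple[str, ...] = ANOVA_INDEXES
    n_bins: int = 5
    n_replicates: int = 10
    seed: int = 1
    alpha: float = 0.05
    min_group_size: int = 2
    ideal_n_pairs: int = 10
    ideal_total_length: float = 100.0
    out_dir: str = "results"

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def indices_table(config: RunConfig) -> pd.DataFrame:
    """Per-taxon index values: computed from raw measurements when given,
    otherwise the packaged published values."""
    if config.measurements is None:
        df = load_karyomorph_table().rename(columns={"subfamily": "group"})
        return df
    meas = read_measurements(config.measurements)
    rows = []
    for k in karyotypes_from_measurements(meas):
        s = indices.index_set(k)
        rows.append(dataclasses.asdict(s))
    return pd.DataFrame(rows)


def values_with_ideals(
    table: pd.DataFrame, index_name: str, config: RunConfig
) -> pd.Series:
    """One index's per-taxon values with the six ideal karyotypes appended
    as pseudo-taxa ``ideal_A`` .. ``ideal_F``."""
    labels = []
    seen: dict[str, int] = {}
    for taxon in table["taxon"]:
        seen[taxon] = seen.get(taxon, 0) + 1
        # taxa listed more than once (same species, different source) stay
        # distinct leaves
        labels.append(taxon if seen[taxon] == 1 else f"{taxon} ({seen[taxon]})")
    vals = pd.Series(table[index_name].to_numpy(), index=labels, dtype=float)
    ideal_vals = {}
    for ik in ideal_series(config.ideal_n_pairs, config.ideal_total_length):
        s = indices.index_set(ik.karyotype)
        ideal_vals[f"ideal_{ik.label}"] = float(getattr(s, index_name))
    return pd.concat([vals, pd.Series(ideal_vals)])


def _write(df: pd.DataFrame, path: Path, config: RunConfig) -> None:
    header = f"# karyoasym {__version__} config {config.config_hash()}\n"
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, index=False)


def run_full_analysis(config: RunConfig) -> dict:
    """Run the full pipeline and write tables/trees under ``config.out_dir``.

    Returns a report bundle: the index table, per-index cluster results and
    per-index ANOVA/Tukey summaries, plus a structured log of row counts
    and seeds.
    """
    out = Path(config.out_dir)
    table = indices_table(config)
    log = [
        {"stage": "indices", "rows": len(table), "seed": None},
    ]
    _write(table, out / "index_table.csv", config)

    cluster_results = {}
    assignments = []
    for name in config.cluster_indexes:
        vals = values_with_ideals(table, name, config)
        res = run_cluster_analysis(
            vals,
            index_name=name,
            n_replicates=config.n_replicates,
            n_bins=config.n_bins,
            seed=config.seed,
        )
        cluster_results[name] = res
        (out / "trees").mkdir(parents=True, exist_ok=True)
        (out / "trees" / f"consensus_{name}.nwk").write_text(res.newick + "\n")
        a = res.nearest_ideal.copy()
        a.insert(0, "index", name)
        assignments.append(a)
        log.append(
            {"stage": f"cluster:{name}", "rows": len(vals), "seed": config.seed}
        )
    _write(pd.concat(assignments, ignore_index=True),
           out / "nearest_ideal.csv", config)

    anova_rows = []
    summaries = []
    tukeys = {}
    for name in config.anova_indexes:
        res = one_way_anova(
            table[name], table["group"], min_group_size=config.min_group_size
        )
        tk = tukey_hsd(
            table[name], table["group"],
            alpha=config.alpha, min_group_size=config.min_group_size,
        )
        tukeys[name] = tk
        anova_rows.append(
            {
                "index": name,
                "f_statistic": res.f_statistic,
                "p_value": res.p_value,
                "df_between": res.df_between,
                "df_within": res.df_within,
                "letters": ";".join(
                    f"{g}={l}" for g, l in sorted(tk.letters.items())
                ),
            }
        )
        for s in summarize_by_group(table[name], table["group"]):
            summaries.append({"index": name, **dataclasses.asdict(s)})
        log.append({"stage": f"anova:{name}", "rows": res.n_used, "seed": None})
    anova_df = pd.DataFrame(anova_rows)
    _write(anova_df, out / "group_anova.csv", config)
    _write(pd.DataFrame(summaries), out / "group_summaries.csv", config)
    (out / "run_log.json").write_text(json.dumps(log, indent=2) + "\n")

    return {
        "index_table": table,
        "cluster": cluster_results,
        "anova": anova_df,
        "tukey": tukeys,
        "log": log,
    }
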