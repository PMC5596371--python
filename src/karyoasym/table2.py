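"""Packaged Orchidaceae karyomorphometry table.

A published compilation of karyomorphometric summaries for 62 orchid
karyotypes across four subfamilies (Cypripedioideae, Epidendroideae,
Orchidoideae, Vanillioideae): diploid number, karyotype formula,
chromosome size range, haploid complement length (hcl) and the asymmetry
indices A2, TF%, Ask%, Syi, A1 and A as printed (two-decimal precision;
values are stored as data, not recomputed).  The accompanying study text
speaks of 64 species; the table itself prints 62 rows, one species
appearing twice from different sources — :func:`validation_report`
surfaces these provenance notes rather than silently resolving them.

The file is checksummed so any transcription edit fails loudly.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from importlib import resources

import pandas as pd

__all__ = ["KaryomorphRecord", "load_karyomorph_table", "load_records",
           "validation_report", "FIXTURE_SHA256"]

FIXTURE_SHA256 = "22c2392fcb640a58c89d4d08bf1f1d0ed10d1a0894725c32eb3ec6fbfedd6a7e"

# One printed row whose karyotype formula does not sum to its printed 2n
# (18M+28S+2A = 48 vs 2n = 46); kept exactly as published.
KNOWN_FORMULA_MISMATCHES = ("Pelexia laxa",)


@dataclass(frozen=True)
class KaryomorphRecord:
    """One published karyomorphometric row."""

    taxon: str
    subfamily: str
    reference: str
    diploid_2n: int
    formula: str
    size_min_um: float
    size_max_um: float
    hcl_um: float
    a2: float
    tf: float
    ask: float
    syi: float
    a1: float
    a_watanabe: float


def _fixture_bytes() -> bytes:
    return (
        resources.files("karyoasym.data")
        .joinpath("orchid_karyomorphometry.csv")
        .read_bytes()
    )


def load_karyomorph_table(*, verify: bool = True) -> pd.DataFrame:
    """The packaged table as a DataFrame (one row per published karyotype)."""
    raw = _fixture_bytes()
    if verify:
        digest = hashlib.sha256(raw).hexdigest()
        if digest != FIXTURE_SHA256:
            raise RuntimeError(
                "packaged karyomorphometry table failed its integrity check "
                f"(sha256 {digest})"
            )
    from io import BytesIO

    return pd.read_csv(BytesIO(raw))


def load_records(*, verify: bool = True) -> list[KaryomorphRecord]:
    df = load_karyomorph_table(verify=verify)
    return [KaryomorphRecord(**row) for row in df.to_dict(orient="records")]


def validation_report() -> dict:
    """Structural facts about the packaged table, including known
    printed-source discrepancies."""
    df = load_karyomorph_table()
    from .model import parse_formula

    mismatches = []
    for _, row in df.iterrows():
        if sum(parse_formula(row["formula"]).values()) != row["diploid_2n"]:
            mismatches.append(row["taxon"])
    dup = df["taxon"][df["taxon"].duplicated()].tolist()
    return {
        "n_rows": int(len(df)),
        "n_unique_taxa": int(df["taxon"].nunique()),
        "rows_per_subfamily": df["subfamily"].value_counts().to_dict(),
        "duplicated_taxa": dup,
        "formula_2n_mismatches": mismatches,
        "stated_species_count_in_source_text": 64,
    }
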