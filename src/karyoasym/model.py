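"""Core data model for chromosome morphometry.

A chromosome is described by its two arm lengths (short arm ``p``, long arm
``q``, both in micrometres).  From these the arm ratio ``r = q/p``, the
centromeric index ``CI = 100*p/(p+q)`` and a morphology class are derived.
Chromosomes are grouped into homologous pairs, and an ordered collection of
pairs for one taxon forms a :class:`Karyotype`.

Morphology classes follow the arm-ratio convention widespread in plant
cytogenetics: metacentric (M, r in [1, 1.5)), submetacentric (S, r in
[1.5, 3)), acrocentric (A, r >= 3) and telocentric (T, r infinite, i.e. no
short arm).  The printed class limits (1.00-1.49 / 1.50-2.99 / >= 3.00) are
read as half-open intervals so that every valid arm ratio receives exactly
one class.  Many studies do not distinguish acrocentric from telocentric
chromosomes; ``merge_telocentric=True`` (the default) reports T as A.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

__all__ = [
    "MORPHOLOGY_CLASSES",
    "classify_arm_ratio",
    "parse_formula",
    "format_formula",
    "Chromosome",
    "HomologPair",
    "Karyotype",
    "build_karyotype",
    "read_measurements",
    "karyotypes_from_measurements",
    "summary_table",
]

#: Morphology class codes in order of increasing asymmetry.
MORPHOLOGY_CLASSES = ("M", "S", "A", "T")

_METACENTRIC_MAX = 1.5   # r below this -> M
_SUBMETACENTRIC_MAX = 3.0  # r below this (and >= 1.5) -> S


def classify_arm_ratio(
    arm_ratio: float,
    *,
    zero_short_arm: bool = False,
    merge_telocentric: bool = True,
) -> str:
    """Classify a chromosome by arm ratio.

    Parameters
    ----------
    arm_ratio:
        Long-arm length divided by short-arm length; must be >= 1 (arms are
        assumed normalized so the short arm is never the longer one).  May be
        ``math.inf`` for a telocentric chromosome.
    zero_short_arm:
        Set when the short arm has zero length (telocentric); equivalent to
        passing ``arm_ratio=math.inf``.
    merge_telocentric:
        Report telocentrics as "A" instead of "T" (common practice when the
        distinction between acrocentric and telocentric is not drawn).

    Returns
    -------
    str
        One of ``"M"``, ``"S"``, ``"A"``, ``"T"``.
    """
    if zero_short_arm or math.isinf(arm_ratio):
        return "A" if merge_telocentric else "T"
    if not arm_ratio >= 1.0:
        raise ValueError(
            f"arm ratio must be >= 1 (arms not normalized?): {arm_ratio!r}"
        )
    if arm_ratio < _METACENTRIC_MAX:
        return "M"
    if arm_ratio < _SUBMETACENTRIC_MAX:
        return "S"
    return "A"


_FORMULA_TERM = re.compile(r"^(\d+)([MSAT])$")


def parse_formula(text: str) -> dict[str, int]:
    """Parse a karyotype formula such as ``"44M+2S"`` into class counts."""
    counts: dict[str, int] = {}
    for term in text.replace(" ", "").split("+"):
        m = _FORMULA_TERM.match(term)
        if m is None:
            raise ValueError(f"cannot parse karyotype-formula term {term!r}")
        n, cls = int(m.group(1)), m.group(2)
        if n <= 0:
            raise ValueError(f"non-positive chromosome count in {term!r}")
        if cls in counts:
            raise ValueError(f"class {cls!r} repeated in formula {text!r}")
        counts[cls] = n
    return counts


def format_formula(counts: dict[str, int]) -> str:
    """Format class counts as a karyotype formula, classes in M,S,A,T order."""
    parts = [
        f"{counts[cls]}{cls}"
        for cls in MORPHOLOGY_CLASSES
        if counts.get(cls, 0) > 0
    ]
    if not parts:
        raise ValueError("empty karyotype formula")
    return "+".join(parts)


@dataclass(frozen=True)
class Chromosome:
    """One chromosome: short arm ``p`` and long arm ``q`` in micrometres.

    Use :meth:`from_arms` to build from raw measurements; it swaps the arms
    if needed so that ``short_arm <= long_arm``.
    """

    short_arm: float
    long_arm: float

    def __post_init__(self) -> None:
        if self.long_arm <= 0:
            raise ValueError("long arm must be positive")
        if self.short_arm < 0:
            raise ValueError("short arm must be non-negative")
        if self.short_arm > self.long_arm:
            raise ValueError(
                "short arm exceeds long arm; use Chromosome.from_arms to normalize"
            )

    @classmethod
    def from_arms(cls, p: float, q: float) -> "Chromosome":
        """Build a chromosome from two arm lengths in either order."""
        if p > q:
            p, q = q, p
        return cls(short_arm=p, long_arm=q)

    @property
    def total_length(self) -> float:
        return self.short_arm + self.long_arm

    @property
    def arm_ratio(self) -> float:
        """Arm ratio r = q/p; infinite for a telocentric (p = 0)."""
        if self.short_arm == 0:
            return math.inf
        return self.long_arm / self.short_arm

    @property
    def centromeric_index(self) -> float:
        """CI = 100 * p / (p + q), in [0, 50]."""
        return 100.0 * self.short_arm / self.total_length

    def morphology(self, *, merge_telocentric: bool = True) -> str:
        return classify_arm_ratio(
            self.arm_ratio,
            zero_short_arm=self.short_arm == 0,
            merge_telocentric=merge_telocentric,
        )


@dataclass(frozen=True)
class HomologPair:
    """A homologous pair: one or two chromosomes sharing a pair id.

    Arm lengths used by per-pair statistics are the means over the members
    (``b_i`` for short arms, ``B_i`` for long arms); a pair with a single
    member (odd chromosome counts do occur in published karyotypes) uses that
    member's arms directly.
    """

    pair_id: str
    members: tuple[Chromosome, ...]

    def __post_init__(self) -> None:
        if not 1 <= len(self.members) <= 2:
            raise ValueError(
                f"pair {self.pair_id!r} must contain 1 or 2 chromosomes, "
                f"got {len(self.members)}"
            )

    @property
    def mean_short(self) -> float:
        """b_i: mean short-arm length over the members (um)."""
        return sum(c.short_arm for c in self.members) / len(self.members)

    @property
    def mean_long(self) -> float:
        """B_i: mean long-arm length over the members (um)."""
        return sum(c.long_arm for c in self.members) / len(self.members)

    @property
    def mean_total(self) -> float:
        return self.mean_short + self.mean_long

    @property
    def arm_ratio(self) -> float:
        if self.mean_short == 0:
            return math.inf
        return self.mean_long / self.mean_short

    @property
    def centromeric_index(self) -> float:
        return 100.0 * self.mean_short / self.mean_total

    def morphology(self, *, merge_telocentric: bool = True) -> str:
        return classify_arm_ratio(
            self.arm_ratio,
            zero_short_arm=self.mean_short == 0,
            merge_telocentric=merge_telocentric,
        )


@dataclass(frozen=True)
class Karyotype:
    """The chromosome complement of one taxon.

    ``pairs`` is stored sorted by decreasing mean total length (stable on
    input order for ties), matching the conventional karyogram ordering.
    """

    taxon: str
    pairs: tuple[HomologPair, ...]
    group: str = ""

    def __post_init__(self) -> None:
        if not self.pairs:
            raise ValueError("karyotype must contain at least one pair")
        ordered = tuple(
            sorted(self.pairs, key=lambda pr: -pr.mean_total)
        )
        object.__setattr__(self, "pairs", ordered)

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    @property
    def chromosomes(self) -> tuple[Chromosome, ...]:
        return tuple(c for pr in self.pairs for c in pr.members)

    @property
    def diploid_number(self) -> int:
        """2n: number of chromosomes listed (members, not pairs)."""
        return sum(len(pr.members) for pr in self.pairs)

    @property
    def hcl(self) -> float:
        """Total haploid complement length: sum of per-pair mean lengths (um)."""
        return sum(pr.mean_total for pr in self.pairs)

    def class_counts(self, *, merge_telocentric: bool = True) -> dict[str, int]:
        counts: dict[str, int] = {}
        for c in self.chromosomes:
            cls = c.morphology(merge_telocentric=merge_telocentric)
            counts[cls] = counts.get(cls, 0) + 1
        return counts

    def formula(self, *, merge_telocentric: bool = True) -> str:
        """Diploid karyotype formula, e.g. ``"44M+2S"``."""
        return format_formula(self.class_counts(merge_telocentric=merge_telocentric))

    @property
    def size_range(self) -> tuple[float, float]:
        """(shortest, longest) mean pair length in um."""
        lengths = [pr.mean_total for pr in self.pairs]
        return min(lengths), max(lengths)


def build_karyotype(
    measurements: list[tuple[object, float, float]],
    *,
    taxon: str = "",
    group: str = "",
) -> Karyotype:
    """Build a :class:`Karyotype` from raw ``(pair_id, arm, arm)`` rows.

    Arms may be given in either order; each row is one chromosome.  Rows
    sharing a pair id become one homologous pair (at most two rows per id).
    """
    if not measurements:
        raise ValueError("no measurements given")
    by_pair: dict[str, list[Chromosome]] = {}
    for pair_id, p, q in measurements:
        by_pair.setdefault(str(pair_id), []).append(Chromosome.from_arms(p, q))
    pairs = tuple(
        HomologPair(pair_id=k, members=tuple(v)) for k, v in by_pair.items()
    )
    return Karyotype(taxon=taxon, group=group, pairs=pairs)


MEASUREMENT_COLUMNS = ["taxon", "group", "pair_id", "short_arm_um", "long_arm_um"]


def read_measurements(path: str | Path) -> pd.DataFrame:
    """Read a per-chromosome measurement table (CSV or TSV, one row per
    chromosome) with columns ``taxon, group, pair_id, short_arm_um,
    long_arm_um``."""
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in MEASUREMENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"measurement table missing columns {missing}")
    return df


def karyotypes_from_measurements(df: pd.DataFrame) -> list[Karyotype]:
    """Group a measurement table into one :class:`Karyotype` per taxon."""
    out = []
    for (taxon, group), sub in df.groupby(["taxon", "group"], sort=False):
        rows = list(
            zip(sub["pair_id"], sub["short_arm_um"], sub["long_arm_um"])
        )
        out.append(build_karyotype(rows, taxon=str(taxon), group=str(group)))
    return out


def summary_table(karyotypes: list[Karyotype]) -> pd.DataFrame:
    """One summary row per karyotype: 2n, formula, size range and hcl."""
    rows = []
    for k in karyotypes:
        lo, hi = k.size_range
        rows.append(
            {
                "taxon": k.taxon,
                "group": k.group,
                "diploid_2n": k.diploid_number,
                "formula": k.formula(),
                "min_chrom_um": lo,
                "max_chrom_um": hi,
                "hcl_um": k.hcl,
            }
        )
    return pd.DataFrame(rows)
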