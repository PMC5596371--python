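"""Karyotype asymmetry statistics.

Intrachromosomal indices (where the centromeres sit):

* ``TF%`` (total form percentage): sum of short-arm lengths over total
  complement length.  0.5 for a fully metacentric complement, 0 for a fully
  telocentric one.
* ``Ask%``: sum of long-arm lengths over total complement length; the
  complement of TF%, so TF% + Ask% = 1.
* ``Syi``: 100 * (mean short-arm length) / (mean long-arm length), which
  reduces to 100 * sum(p) / sum(q).
* ``A1``: 1 - mean over homologous pairs of b_i / B_i, where b_i and B_i are
  the pair-mean short and long arms.
* ``A`` (also called M_CA when scaled by 100): mean over pairs of
  (B_i - b_i) / (B_i + b_i).

Interchromosomal index:

* ``A2``: coefficient of variation (sd / mean) of chromosome lengths,
  computed over the per-pair mean total lengths.

``CV_CI`` applies the same coefficient of variation to the centromeric
index.  Note it measures heterogeneity of centromere position among
chromosomes, not intrachromosomal asymmetry proper: a complement of
uniformly telocentric chromosomes has CV_CI near 0 despite maximal
asymmetry.

Categorical summaries: the classical 3x4 karyotype-category grid
(:func:`stebbins_category`) and a coarse three-level asymmetry degree
(:func:`degree_class`) based on the percentage of acrocentric/telocentric
chromosomes.
"""

from __future__ import annotations

import math
import statistics
from dataclasses import dataclass

from .model import Karyotype

__all__ = [
    "tf_fraction",
    "ask_fraction",
    "syi",
    "a1",
    "a_watanabe",
    "a2",
    "cv_ci",
    "stebbins_category",
    "degree_class",
    "IndexSet",
    "index_set",
]


def tf_fraction(k: Karyotype) -> float:
    """TF%: sum of short arms over total complement length (fraction in [0, 0.5])."""
    chroms = k.chromosomes
    total = sum(c.total_length for c in chroms)
    return sum(c.short_arm for c in chroms) / total


def ask_fraction(k: Karyotype) -> float:
    """Ask%: sum of long arms over total complement length (fraction in [0.5, 1])."""
    chroms = k.chromosomes
    total = sum(c.total_length for c in chroms)
    return sum(c.long_arm for c in chroms) / total


def syi(k: Karyotype) -> float:
    """Symmetry index Syi = 100 * sum(p) / sum(q), in (0, 100]."""
    chroms = k.chromosomes
    return 100.0 * sum(c.short_arm for c in chroms) / sum(c.long_arm for c in chroms)


def a1(k: Karyotype) -> float:
    """Intrachromosomal asymmetry A1 = 1 - mean_i(b_i / B_i) over pairs."""
    return 1.0 - sum(pr.mean_short / pr.mean_long for pr in k.pairs) / k.n_pairs


def a_watanabe(k: Karyotype) -> float:
    """Asymmetry index A = mean_i((B_i - b_i) / (B_i + b_i)) over pairs."""
    return (
        sum((pr.mean_long - pr.mean_short) / pr.mean_total for pr in k.pairs)
        / k.n_pairs
    )


def a2(k: Karyotype, *, ddof: int = 1) -> float:
    """Interchromosomal asymmetry A2 = sd / mean of chromosome lengths.

    Computed over per-pair mean total lengths.  ``ddof=1`` (sample standard
    deviation) by default; pass ``ddof=0`` for the population form.
    """
    if k.n_pairs < 2:
        raise ValueError("A2 requires at least 2 pairs")
    lengths = [pr.mean_total for pr in k.pairs]
    mean = statistics.fmean(lengths)
    sd = statistics.stdev(lengths) if ddof == 1 else statistics.pstdev(lengths)
    return sd / mean


def cv_ci(k: Karyotype, *, ddof: int = 1) -> float:
    """Coefficient of variation of the centromeric index, in percent."""
    if k.n_pairs < 2:
        raise ValueError("CV_CI requires at least 2 pairs")
    cis = [pr.centromeric_index for pr in k.pairs]
    mean = statistics.fmean(cis)
    if mean == 0:
        raise ValueError("CV_CI undefined for an all-telocentric complement")
    sd = statistics.stdev(cis) if ddof == 1 else statistics.pstdev(cis)
    return 100.0 * sd / mean


def _high_ratio_proportion(k: Karyotype) -> float:
    """Proportion of chromosomes with arm ratio >= 2 (telocentrics count)."""
    chroms = k.chromosomes
    return sum(1 for c in chroms if c.arm_ratio >= 2.0) / len(chroms)


def stebbins_category(k: Karyotype, *, literal_header: bool = False) -> str:
    """Karyotype category in the 3x4 grid "1A" .. "3D".

    The digit encodes the largest/smallest chromosome size ratio (< 2:1 ->
    1; 2:1 to 4:1 -> 2; > 4:1 -> 3).  The letter encodes the proportion of
    chromosomes whose arm ratio is at least 2:1 (0 -> A, up to half -> B,
    more than half but not all -> C, all -> D), i.e. the share of strongly
    asymmetric chromosomes.  ``literal_header=True`` instead grades the
    proportion of chromosomes with arm ratio *below* 2:1, for compatibility
    with sources that tabulate the grid that way.
    """
    lo, hi = k.size_range
    ratio = hi / lo
    if ratio < 2.0:
        digit = "1"
    elif ratio <= 4.0:
        digit = "2"
    else:
        digit = "3"
    prop = _high_ratio_proportion(k)
    if literal_header:
        prop = 1.0 - prop
    if prop == 0.0:
        letter = "A"
    elif prop <= 0.5:
        letter = "B"
    elif prop < 1.0:
        letter = "C"
    else:
        letter = "D"
    return digit + letter


def degree_class(k: Karyotype) -> str:
    """Coarse asymmetry degree from the percentage of A/T chromosomes.

    SA (slightly asymmetric) up to 30%, MA (moderately) above 30 up to 50%,
    StA (strongly) above 50%.
    """
    chroms = k.chromosomes
    pct = 100.0 * sum(
        1 for c in chroms if c.morphology(merge_telocentric=True) == "A"
    ) / len(chroms)
    if pct <= 30.0:
        return "SA"
    if pct <= 50.0:
        return "MA"
    return "StA"


@dataclass(frozen=True)
class IndexSet:
    """All asymmetry statistics for one karyotype.

    ``tf``, ``ask``, ``a1`` and ``a_watanabe`` are fractions; ``syi`` and
    ``cv_ci`` are percentages; ``a2`` is dimensionless; ``hcl`` is in um.
    ``a2`` and ``cv_ci`` are NaN for single-pair complements (undefined
    dispersion).
    """

    taxon: str
    group: str
    diploid_2n: int
    formula: str
    tf: float
    ask: float
    syi: float
    a1: float
    a_watanabe: float
    a2: float
    cv_ci: float
    stebbins: str
    degree: str
    hcl: float


def index_set(k: Karyotype, *, ddof: int = 1) -> IndexSet:
    """Compute the full set of asymmetry statistics for one karyotype."""
    if k.n_pairs >= 2:
        a2_val = a2(k, ddof=ddof)
        try:
            cv = cv_ci(k, ddof=ddof)
        except ValueError:
            cv = math.nan
    else:
        a2_val = math.nan
        cv = math.nan
    return IndexSet(
        taxon=k.taxon,
        group=k.group,
        diploid_2n=k.diploid_number,
        formula=k.formula(),
        tf=tf_fraction(k),
        ask=ask_fraction(k),
        syi=syi(k),
        a1=a1(k),
        a_watanabe=a_watanabe(k),
        a2=a2_val,
        cv_ci=cv,
        stebbins=stebbins_category(k),
        degree=degree_class(k),
        hcl=k.hcl,
    )
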