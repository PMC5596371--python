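"""Ideal reference karyotypes A-F.

Six synthetic karyotypes spanning the full intrachromosomal asymmetry
range, used as comparative standards in clustering: A is fully symmetric
(all metacentric, arm ratio 1) and F fully asymmetric (all telocentric),
with B-E an increasing arm-ratio ladder in between.  All chromosomes within
an ideal karyotype have equal length, so the ideals carry no
interchromosomal asymmetry and differ only in centromere position.

The default ladder (arm ratios 1.0, 1.4, 2.0, 4.0, 9.0, infinity) walks
through every morphology class (M, M, S, A, A, T) and makes every
intrachromosomal index strictly monotone from A to F.  Alternative ladders
can be passed explicitly where a different reference model is wanted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .model import Chromosome, HomologPair, Karyotype

__all__ = [
    "IDEAL_LABELS",
    "DEFAULT_ARM_RATIOS",
    "IdealKaryotype",
    "make_ideal",
    "ideal_series",
    "ideogram_coords",
]

IDEAL_LABELS = ("A", "B", "C", "D", "E", "F")

#: Arm ratio used for every chromosome of each ideal karyotype.
DEFAULT_ARM_RATIOS: dict[str, float] = {
    "A": 1.0,
    "B": 1.4,
    "C": 2.0,
    "D": 4.0,
    "E": 9.0,
    "F": math.inf,
}


@dataclass(frozen=True)
class IdealKaryotype:
    label: str
    karyotype: Karyotype
    arm_ratio: float

    @property
    def description(self) -> str:
        r = "inf" if math.isinf(self.arm_ratio) else f"{self.arm_ratio:g}"
        return f"ideal karyotype {self.label}: uniform arm ratio {r}"


def make_ideal(
    label: str,
    n_pairs: int = 10,
    total_length: float = 100.0,
    *,
    arm_ratios: dict[str, float] | None = None,
) -> IdealKaryotype:
    """Build one ideal karyotype.

    Parameters
    ----------
    label:
        One of ``"A"`` .. ``"F"``.
    n_pairs:
        Number of homologous pairs (all identical); must be >= 2 so that
        dispersion statistics are defined.
    total_length:
        Haploid complement length (hcl) in um; every chromosome has length
        ``total_length / n_pairs``.
    arm_ratios:
        Optional replacement for :data:`DEFAULT_ARM_RATIOS`.
    """
    ratios = DEFAULT_ARM_RATIOS if arm_ratios is None else arm_ratios
    if label not in ratios:
        raise ValueError(f"unknown ideal karyotype label {label!r}")
    if n_pairs < 2:
        raise ValueError("an ideal karyotype needs at least 2 pairs")
    r = ratios[label]
    length = total_length / n_pairs
    if math.isinf(r):
        p, q = 0.0, length
    else:
        p = length / (1.0 + r)
        q = length - p
    chrom = Chromosome(short_arm=p, long_arm=q)
    pairs = tuple(
        HomologPair(pair_id=str(i + 1), members=(chrom, chrom))
        for i in range(n_pairs)
    )
    return IdealKaryotype(
        label=label,
        karyotype=Karyotype(taxon=f"ideal_{label}", group="ideal", pairs=pairs),
        arm_ratio=r,
    )


def ideal_series(
    n_pairs: int = 10,
    total_length: float = 100.0,
    *,
    arm_ratios: dict[str, float] | None = None,
) -> list[IdealKaryotype]:
    """All six ideal karyotypes A-F with shared geometry."""
    labels = IDEAL_LABELS if arm_ratios is None else tuple(arm_ratios)
    return [
        make_ideal(lab, n_pairs, total_length, arm_ratios=arm_ratios)
        for lab in labels
    ]


def ideogram_coords(k: Karyotype | IdealKaryotype) -> list[tuple[int, float, float]]:
    """Ideogram coordinates: ``(rank, short-arm span, long-arm span)`` per
    pair, in um, ranked by decreasing total length."""
    if isinstance(k, IdealKaryotype):
        k = k.karyotype
    return [
        (rank, pr.mean_short, pr.mean_long)
        for rank, pr in enumerate(k.pairs, start=1)
    ]
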