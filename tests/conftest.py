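import numpy as np
import pytest

from karyoasym.model import Chromosome, HomologPair, Karyotype, build_karyotype


def random_karyotype(rng: np.random.Generator, *, n_pairs: int | None = None,
                     allow_telocentric: bool = True) -> Karyotype:
    """A random valid karyotype for property tests."""
    if n_pairs is None:
        n_pairs = int(rng.integers(2, 31))
    pairs = []
    for i in range(n_pairs):
        total = float(rng.uniform(0.5, 20.0))
        if allow_telocentric and rng.random() < 0.1:
            p = 0.0
        else:
            p = float(rng.uniform(0.0, total / 2.0))
        chrom = Chromosome(short_arm=p, long_arm=total - p)
        pairs.append(HomologPair(pair_id=str(i + 1), members=(chrom, chrom)))
    return Karyotype(taxon="random", pairs=tuple(pairs))


@pytest.fixture
def two_pair_karyotype() -> Karyotype:
    """The hand-computable reference complement: arms (1,1) and (1,3)."""
    return build_karyotype([("1", 1.0, 1.0), ("2", 1.0, 3.0)])


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260417)
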