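import numpy as np
import pytest

from mitorec.circular_alignment import align
from mitorec.marker_calling import call_markers
from mitorec.synthetic_data import simulate_parent_pair

BASES = np.array(list("ACGT"))


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[rng.integers(0, 4, n)])


def mutate(seq: str, rng: np.random.Generator, n_subs: int = 0,
           indels: list[tuple[int, int]] | None = None) -> str:
    """Derived sequence with n_subs random substitutions and the given
    (position, signed length) indels (negative = deletion)."""
    s = list(seq)
    for p in rng.choice(len(s) - 1, size=n_subs, replace=False):
        s[p] = str(rng.choice([b for b in "ACGT" if b != s[p]]))
    out = "".join(s)
    for pos, ln in sorted(indels or [], reverse=True):
        if ln < 0:
            out = out[:pos] + out[pos - ln:]
        else:
            out = out[:pos] + random_dna(rng, ln) + out[pos:]
    return out


@pytest.fixture(scope="session")
def parent_pair():
    """Default-scale parental pair with planted truth (seed 7)."""
    return simulate_parent_pair(seed=7)


@pytest.fixture(scope="session")
def parent_aln(parent_pair):
    ga, gb, _ = parent_pair
    return align(ga, gb)


@pytest.fixture(scope="session")
def parent_markers(parent_aln):
    return call_markers(parent_aln)
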