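import numpy as np
import pytest
from scipy.integrate import quad

from straincomp.models import MODELS
from straincomp.regions import RegionSet
from straincomp.synthetic import simulate_genome_set


def quadrature_auc(model, A, mu, lam, y0, t_max=72.0):
    """Independent oracle: adaptive quadrature of the closed form minus baseline."""
    val, _ = quad(
        lambda t: float(MODELS[model](np.array([t]), A, mu, lam, y0)[0]) - y0,
        0, t_max, limit=400,
    )
    return val


def bool_cover(intervals, length):
    """Per-base boolean coverage oracle."""
    arr = np.zeros(length, dtype=bool)
    for s, e in intervals:
        arr[s:e] = True
    return arr


def regions_from_bool(arr):
    """Intervals of True runs in a boolean array (independent oracle)."""
    out = []
    idx = np.flatnonzero(np.diff(np.concatenate(([0], arr.view(np.int8), [0]))))
    for s, e in zip(idx[::2], idx[1::2]):
        out.append((int(s), int(e)))
    return out


@pytest.fixture(scope="session")
def tiled_six_genomes():
    """Six genomes whose shared + unique blocks exactly tile every replicon.

    Layout per genome: three 4-kb blocks shared by all six, one 3-kb
    block shared with the next genome around a ring, one 3-kb block
    shared with the previous genome, then two 4-kb + one 2-kb
    genome-unique blocks.  Total 28 kb; genome g1 is split into two
    replicons (18 kb shared + 10 kb unique) to exercise pooling over
    replicons.
    """
    shared = [(4000, list(range(6))) for _ in range(3)]
    shared += [(3000, [i, (i + 1) % 6]) for i in range(6)]
    unique = []
    for g in range(6):
        unique += [(4000, g), (4000, g), (2000, g)]
    plan = [[18000, 10000]] + [[28000]] * 5
    genomes, truths = simulate_genome_set(6, plan, shared, unique, seed=42)
    return genomes, truths


def planted_unique(truth) -> RegionSet:
    return truth.planted_unique_regions
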