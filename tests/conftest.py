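import numpy as np
import pytest

from corecc import zsi_fixture


@pytest.fixture
def zsi_tree():
    return zsi_fixture()


@pytest.fixture
def rng():
    return np.random.default_rng(20260101)


def random_tree(rng):
    """Random assessment tree as plain nested data (for oracle comparison).

    Structure: list of dimensions, each {"mode": flat|nested, "factors":
    [[(p, s), ...], ...]} with up to 20 indicators total.
    """
    n_dims = int(rng.integers(1, 5))
    dims = []
    for _ in range(n_dims):
        n_factors = int(rng.integers(1, 4))
        factors = []
        for _ in range(n_factors):
            n_ind = int(rng.integers(1, 4))
            pairs = [
                (float(rng.uniform(0, 3)), float(rng.uniform(0.1, 3)))
                for _ in range(n_ind)
            ]
            factors.append(pairs)
        mode = "nested" if rng.random() < 0.5 else "flat"
        dims.append({"mode": mode, "factors": factors})
    return dims


def oracle_assess(dims):
    """Independent direct evaluation of the surplus-ratio chain.

    Plain-python re-derivation: d = 1 - p/s per indicator, 1 - RMS(1 - d)
    pooling per level, nested vs flat per dimension.  Returns
    (dimension ratios, overall ratio).
    """
    import math

    def pool(values):
        return 1.0 - math.sqrt(sum((1.0 - v) ** 2 for v in values) / len(values))

    dim_ratios = []
    for dim in dims:
        if dim["mode"] == "nested":
            fr = [pool([1.0 - p / s for (p, s) in f]) for f in dim["factors"]]
            dim_ratios.append(pool(fr))
        else:
            ds = [1.0 - p / s for f in dim["factors"] for (p, s) in f]
            dim_ratios.append(pool(ds))
    return dim_ratios, pool(dim_ratios)


def build_corecc_tree(dims):
    """Build the package's AssessmentTree from the plain structure."""
    from corecc import AggregationMode, AssessmentTree, Dimension, Factor, IndicatorPair

    out = []
    k = 0
    for di, dim in enumerate(dims):
        factors = []
        for fi, f in enumerate(dim["factors"]):
            inds = []
            for (p, s) in f:
                k += 1
                inds.append(IndicatorPair(id=f"i{k}", name=f"i{k}", pressure=p, support=s))
            factors.append(Factor(id=f"f{di}_{fi}", name=f"f{di}_{fi}", indicators=inds))
        out.append(
            Dimension(
                id=f"d{di}",
                name=f"d{di}",
                aggregation_mode=AggregationMode(dim["mode"]),
                factors=factors,
            )
        )
    return AssessmentTree(dimensions=out)
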