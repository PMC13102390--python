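import numpy as np
import pytest

from antnest import demography as dg
from antnest import excavation as ex


@pytest.fixture(scope="session")
def params() -> ex.ModelParams:
    return ex.ModelParams()


def make_cohort_timeline(n_workers: int, age: float, duration: float = 45.0,
                         with_queen: bool = False,
                         queen_age: float = 365.0) -> dg.ColonyTimeline:
    """Fixed-demographics timeline of same-age workers, optionally a queen."""
    ants = []
    if with_queen:
        ants.append(dg.AntRecord("queen", dg.QUEEN, -queen_age))
    ants += [dg.AntRecord(f"w{i:02d}", dg.WORKER, -age) for i in range(n_workers)]
    return dg.ColonyTimeline(ants, duration, "fixed",
                             np.arange(0.0, duration + 0.5))


@pytest.fixture(scope="session")
def maturation_ensemble(params):
    """22 synthetic maturation colonies with noise-free sampled observations."""
    root = np.random.default_rng(2024)
    cfg = dg.GeneratorConfig(seed=2024)
    out = []
    for _ in range(22):
        rng = np.random.default_rng(root.integers(2 ** 31))
        tl = dg.synth_maturation_colony(cfg, rng=rng)
        res = ex.simulate(tl, params)
        obs = ex.observe(res, tl.sampling_days, 0.0, rng)
        out.append((tl, res, obs))
    return out
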