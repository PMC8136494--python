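import numpy as np
import pytest

from neoy.sim import SimConfig, simulate_history, simulate_population


def small_sim_config(seed: int = 0, **kw) -> SimConfig:
    """A fast, structurally complete simulation: all five sections, both
    PARs, inversion, genes, expression — at reduced sizes."""
    defaults = dict(
        strata_x1=((300_000, 55e6), (300_000, 28e6), (300_000, 55e6)),
        strata_x2=((300_000, 48e6),),
        gradient_len=400_000,
        par_lengths=(100_000, 100_000),
        fusion_spacer=20_000,
        autosome_len=400_000,
        n_males=6,
        n_females=8,
        n_genes=40,
        n_auto_genes=12,
        hdxy_count=3,
        yxminus_count=2,
        lost_count=4,
        pseudo_rate=0.1,
        deg_count=10,
        seed=seed,
    )
    defaults.update(kw)
    return SimConfig(**defaults)


@pytest.fixture(scope="session")
def small_history():
    return simulate_history(small_sim_config(seed=7))


@pytest.fixture(scope="session")
def small_population(small_history):
    return simulate_population(small_history.cfg, small_history)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
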