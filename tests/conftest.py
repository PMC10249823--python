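import numpy as np
import pytest

from hicreg.sim import CompartmentBlock, SimConfig, TadSegment


def tad_only_config(seed: int, fold: float = 3.0, n_tads: int = 20,
                    **kw) -> SimConfig:
    """20 planted TADs of 40 bins on the default 20 Mb / 20 kb chromosome."""
    tads = [TadSegment(60 + k * 42, 100 + k * 42, fold) for k in range(n_tads)]
    return SimConfig(tad_segments=tads, seed=seed, **kw)


def checkerboard_config(seed: int, strength: float = 1.5, flip_block: int | None = None,
                        **kw) -> SimConfig:
    """Alternating 50-bin A/B blocks over 1000 bins; optionally one block
    flips label in stage 1."""
    blocks = [CompartmentBlock(k * 50, min(1000, (k + 1) * 50),
                               "A" if k % 2 == 0 else "B",
                               (1,) if k == flip_block else ())
              for k in range(20)]
    return SimConfig(compartment_blocks=blocks, compartment_strength=strength,
                     seed=seed, **kw)


@pytest.fixture(scope="session")
def balanced_tad_matrix():
    """One balanced pooled matrix from the planted-TAD scenario (shared
    across read-only tests)."""
    from hicreg.matrix import kr_balance, pool
    from hicreg.sim import simulate_contact_map

    cfg = tad_only_config(seed=11)
    m = pool([simulate_contact_map(cfg, 0, r)[0] for r in range(2)])
    kr_balance(m)
    return m, cfg


@pytest.fixture
def rng():
    return np.random.default_rng(0)
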