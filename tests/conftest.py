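import numpy as np
import pytest

from triokit.pedigree import TrioPedigree
from triokit.simulate import SimConfig, simulate_cnv_callsets, simulate_sites


@pytest.fixture(scope="session")
def trios5() -> list[TrioPedigree]:
    return [
        TrioPedigree(p, f"{p}_fa", f"{p}_mo", f"{p}_ch", p)
        for p in ("BTQ", "MDQ", "SMI", "DSN", "MRT")
    ]


@pytest.fixture(scope="session")
def small_dataset():
    """5 trios x 20k sites with planted de novo events (shared, read-only)."""
    return simulate_sites(SimConfig(n_sites=20_000, seed=7))


@pytest.fixture(scope="session")
def clean_cnv_sim():
    """CNV call sets with no breakpoint jitter and no caller dropout."""
    cfg = SimConfig(n_sites=1_000, cnv_jitter_frac=0.0, cnv_dropout=0.0, seed=13)
    return simulate_cnv_callsets(cfg)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20_240_917)
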