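import numpy as np
import pytest

import optogate as og


@pytest.fixture
def quiet_emitter() -> og.EmitterModel:
    """Gating-only emitter: no blinking, no bleaching, SNR 10."""
    return og.EmitterModel(
        k_open_max=4.0, k_close=6.41, ec50=0.33, hill_n=2.0,
        k_blink_off=0.0, k_blink_on=0.0, k_bleach=0.0,
        brightness=10.0, bg_mean=100.0, bg_sd=1.0,
    )


@pytest.fixture(scope="session")
def open_fixture() -> og.PoreFixture:
    return og.make_pore_fixture("open", n_frames=10, seed=11)


@pytest.fixture(scope="session")
def closed_fixture() -> og.PoreFixture:
    return og.make_pore_fixture("closed", n_frames=10, seed=12)


def make_ensemble(coords, radii, resnames=None):
    """Single-frame PoreEnsemble from bare coordinates and radii."""
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[-2]
    resnames = np.asarray(resnames) if resnames is not None else np.array(["RES"] * n)
    return og.PoreEnsemble(
        coordinates=coords[None] if coords.ndim == 2 else coords,
        resnames=resnames,
        atomnames=np.array(["C"] * n),
        chain_ids=np.array(["A"] * n),
        resids=np.arange(n),
        vdw_radii=np.asarray(radii, dtype=float),
    )
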