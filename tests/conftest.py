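import numpy as np
import pytest

from waxprint import simulate, tis


def build_matrix(seed: int, noise_sd: float = 0.02, lot_sd: float = 0.05,
                 marker_table=None):
    """Generate a full 75-run study and assemble its normalized TIS matrix."""
    kwargs = {"noise_sd": noise_sd, "lot_sd": lot_sd, "seed": seed}
    if marker_table is not None:
        kwargs["marker_table"] = marker_table
    params = simulate.GeneratorParams(**kwargs)
    runs, meta = simulate.make_study(params, seed=seed)
    spectra = []
    for run, row in zip(runs, meta.itertuples(index=False)):
        t = tis.base_peak_normalize(tis.collapse_to_tis(run))
        t.lot, t.blend_pct, t.replicate = row.lot, row.blend_pct, row.replicate
        spectra.append(t)
    return tis.assemble_matrix(spectra), meta


@pytest.fixture(scope="session")
def study_matrix():
    """One default-parameter study shared across tests (seed 1)."""
    return build_matrix(seed=1)


@pytest.fixture(scope="session")
def quiet_matrix():
    """A low-noise study for planted-structure recovery checks."""
    return build_matrix(seed=1, noise_sd=0.005, lot_sd=0.02)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
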