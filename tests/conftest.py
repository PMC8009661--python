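import warnings

import numpy as np
import pytest

from na_dynamics import synthetic as syn, tfm
from na_dynamics.config import ImagingConfig

# the L1 solver's non-convergence warning at extreme lambdas is expected in
# path/property tests and asserted explicitly where it matters
warnings.filterwarnings("ignore", message="L1 solver did not reach")


@pytest.fixture(scope="session")
def config() -> ImagingConfig:
    return ImagingConfig()


@pytest.fixture(scope="session")
def edge(config) -> syn.SinusoidalEdge:
    return syn.SinusoidalEdge(y0_um=32.0, config=config)


@pytest.fixture(scope="session")
def planted_scenario(config, edge):
    """30 tracks per class on a 40x40 µm field, sparse bead field."""
    return syn.plant_tracks({c: 30 for c in syn.CLASS_NAMES}, edge, config,
                            seed=5, n_frames=600, bead_density_per_um2=0.2)


@pytest.fixture(scope="session")
def planted_tracks(planted_scenario, config):
    return syn.tracks_from_truth(planted_scenario, config, snr=10.0, seed=6)


@pytest.fixture(scope="session")
def single_patch_recovery(config):
    """Render -> PIV -> L-curve -> L1 inversion of one 300 Pa patch.

    Shared by the TFM oracle tests; computed once per session.
    """
    E, nu = config.youngs_modulus_pa, config.poisson_ratio
    beads = syn.generate_bead_field(1.0, (20, 20), 0.3, seed=3)
    patch = syn.TractionPatch((10.0, 10.0), 300.0, 1.0, (1.0, 0.0),
                              -100.0, 10.0)
    truth = syn.ScenarioTruth([], [patch], beads, (20, 20), 1, seed=3)
    _, bead_stack, ref = syn.render_movie(truth, config, noise=(0.0, 0.0),
                                          seed=4)
    fld = tfm.track_beads(bead_stack[0], ref, template_px=19, max_disp_px=10)
    fld = tfm.remove_outliers(fld)
    fmap = tfm.build_forward_map(fld.positions * config.pixel_size_um,
                                 (0, 0, 20, 20), 1.0, E, nu)
    lam, info = tfm.select_lambda_lcurve(fmap, fld,
                                         np.logspace(-6, -2, 12),
                                         config.pixel_size_um)
    sol = tfm.solve_l1(fmap, fld, lam, config.pixel_size_um)
    return {"patch": patch, "truth": truth, "bead_stack": bead_stack,
            "reference": ref, "field": fld, "fmap": fmap, "lam": lam,
            "lcurve": info, "solution": sol}
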