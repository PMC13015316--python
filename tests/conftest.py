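import numpy as np
import pytest

from protrudyn.simulate import ProtrusionScript, SimulationParams, simulate_cell


@pytest.fixture(scope="session")
def quiet_cell():
    """Circle cell, no protrusions, no noise: the identity fixture."""
    params = SimulationParams(
        n_frames=6,
        centroid_speed=0.2,
        direction_persistence=0.95,
        noise_gaussian_sigma=0.0,
        psf_sigma=0.0,
        seed=42,
    )
    return params, *simulate_cell(params)


@pytest.fixture(scope="session")
def bump_cell():
    """One scripted front protrusion (E/S/R = 12/18/12 s at 6 s frames)."""
    params = SimulationParams(
        n_frames=16,
        centroid_speed=0.2,
        direction_persistence=0.95,
        noise_gaussian_sigma=0.0,
        seed=7,
        protrusion_schedule=[
            ProtrusionScript(
                birth_frame=4, angle=None, amplitude=1.5,
                e_duration=12.0, s_duration=18.0, r_duration=12.0,
            )
        ],
    )
    return params, *simulate_cell(params)


@pytest.fixture(scope="session")
def rendered_quiet(quiet_cell):
    from protrudyn.simulate import render_movie

    params, series, intensity, truth = quiet_cell
    return params, truth, render_movie(series, intensity, params)
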