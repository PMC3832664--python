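import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from nb4d.params import SegmentationConfig, default_imaging, type_i_preset
from nb4d.simulate import make_bystanders, render_movie, simulate_lineage


@pytest.fixture(scope="session")
def clean_render():
    """Noise-free, PSF-free short type I movie with ground truth (oracle
    regime for segmentation tests)."""
    params = type_i_preset(seed=3)
    imaging = default_imaging(seed=4, psf_sigma_xy=0.0, psf_sigma_z=0.0)
    duration = 90.0
    cells = simulate_lineage(params, duration) + make_bystanders(imaging, duration)
    movie, labels = render_movie(cells, imaging, duration, noise=False, blur=False)
    return {"cells": cells, "movie": movie, "labels": labels,
            "params": params, "imaging": imaging}


@pytest.fixture(scope="session")
def noisy_render():
    """Default-noise short type I movie with ground truth."""
    params = type_i_preset(seed=3)
    imaging = default_imaging(seed=4)
    duration = 120.0
    cells = simulate_lineage(params, duration) + make_bystanders(imaging, duration)
    movie, labels = render_movie(cells, imaging, duration, noise=True)
    return {"cells": cells, "movie": movie, "labels": labels,
            "params": params, "imaging": imaging}


@pytest.fixture(scope="session")
def seg_config():
    return SegmentationConfig()
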