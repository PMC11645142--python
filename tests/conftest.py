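import numpy as np
import pytest

import apicoloc as ap


@pytest.fixture(scope="session")
def clean_tissue():
    """Noiseless, blur-free tissue section with ground truth (default geometry)."""
    spec = ap.TissueSpec(seed=101, noise_sd=0.0, psf_sigma_um=0.0)
    channels, gt = ap.generate_tissue(spec)
    return spec, channels, gt


@pytest.fixture(scope="session")
def noisy_tissue():
    """Tissue section at the default noise and PSF settings."""
    spec = ap.TissueSpec(seed=202)
    channels, gt = ap.generate_tissue(spec)
    return spec, channels, gt


@pytest.fixture(scope="session")
def small_4i():
    """Noiseless 3-cycle 4i stack with known shifts, compartments and a
    correlated marker pair."""
    spec = ap.FourISpec(
        seed=7, image_size_px=(320, 320), n_cells=16, n_cycles=3,
        cycle_shifts_px=[(0, 0), (5, -3), (-2, 7)], max_shift_px=10,
        noise_sd=0.0,
        target_correlations={("MARK1", "MARK2"): 0.6},
        compartment_fractions={"COPB2": 0.5, "RAB7": 0.3},
        channel_plan=[["DAPI", "UMOD"], ["DAPI", "CANX"],
                      ["DAPI", "COPB2", "RAB7", "MARK1", "MARK2"]],
    )
    stack, gt = ap.generate_4i_stack(spec)
    return spec, stack, gt


def label_disk(shape, cy, cx, r, arr=None, label=1):
    """Paint a labelled disk into an integer array (test helper)."""
    if arr is None:
        arr = np.zeros(shape, dtype=np.int32)
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    arr[(yy - cy) ** 2 + (xx - cx) ** 2 <= r**2] = label
    return arr
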