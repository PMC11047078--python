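import numpy as np
import pytest

from scnwave import stack_io, synth


@pytest.fixture(scope="session")
def noise_free_stack():
    """Noise-free 48x48 stack, tau=23.3 h, 5 days at 0.5 h sampling."""
    params = synth.SynthParams(
        grid_shape=(48, 48),
        n_frames=240,
        frame_interval_h=0.5,
        baseline_period_h=23.3,
        noise_model="gaussian",
        gaussian_sd=0.0,
        seed=1,
    )
    stack, gt = synth.generate_stack(params)
    return stack, gt, params


@pytest.fixture(scope="session")
def banded_stack():
    """48x48 stack with 5 planted phase bands spanning 8 h, Poisson noise."""
    params = synth.SynthParams(
        grid_shape=(48, 48),
        n_frames=240,
        phase_span_h=8.0,
        n_phase_bands=5,
        noise_model="poisson",
        seed=3,
    )
    stack, gt = synth.generate_stack(params)
    return stack, gt, params


@pytest.fixture(scope="session")
def banded_rois(banded_stack):
    stack, gt, _ = banded_stack
    detrended = stack_io.moving_average_detrend(stack, 24.5)
    rois = stack_io.tile_rois(detrended, gt.tissue_mask)
    norm = stack_io.normalize_series(rois.series)
    return rois, norm.values, gt


@pytest.fixture(scope="session")
def dual_stacks():
    """Dual-reporter 32x32 stack pair with a planted 4 h lag."""
    params = synth.SynthParams(
        grid_shape=(32, 32),
        n_frames=240,
        n_reporters=2,
        reporter_lag_h=4.0,
        noise_model="poisson",
        seed=5,
    )
    (stack_a, stack_b), gt = synth.generate_stack(params)
    return stack_a, stack_b, gt


@pytest.fixture(scope="session")
def three_epoch_schedule():
    return stack_io.TemperatureSchedule(
        [(0.0, 72.0, 37.0), (72.0, 144.0, 32.0), (144.0, 216.0, 37.0)]
    )


def roi_truth_labels(rois, gt):
    """Planted band label at each retained ROI center (-1 = unlabeled)."""
    return gt.cluster_labels[rois.roi_centers[:, 0], rois.roi_centers[:, 1]]
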