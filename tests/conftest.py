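import logging

import numpy as np
import pytest

from fwlesion.gradients import make_gradient_table
from fwlesion.io import DWIVolume
from fwlesion.phantom import simulate_voxel_signal
from fwlesion import csd as csd_mod

logging.getLogger("fwlesion").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def gtab30():
    """Typical clinical single-shell scheme: 1 b0 + 30 directions at b=1000."""
    return make_gradient_table(30, 1000.0, 1, seed=7)


@pytest.fixture(scope="session")
def gtab60():
    """Denser scheme that supports lmax=8 deconvolution."""
    return make_gradient_table(60, 1000.0, 2, seed=3)


@pytest.fixture(scope="session")
def fiber_tensor():
    return np.diag([1.7e-3, 0.3e-3, 0.3e-3])  # single fiber along +x


def _calibration_volume(gtab):
    """A tiny volume with pure fiber / GM-like / CSF-like voxel blocks, used
    to estimate three-tissue responses."""
    s0 = 100.0
    tfib = np.diag([1.7e-3, 0.3e-3, 0.3e-3])
    sig_fib = simulate_voxel_signal(0.0, tfib, gtab, s0)
    sig_gm = s0 * np.exp(-gtab.bvals * 1.2e-3)
    sig_csf = s0 * np.exp(-gtab.bvals * 3.0e-3)
    data = np.zeros((60, 3, 1, len(gtab)))
    data[:, 0, 0] = sig_fib
    data[:, 1, 0] = sig_gm
    data[:, 2, 0] = sig_csf
    masks = {k: np.zeros(data.shape[:3], bool) for k in ("wm", "gm", "csf")}
    masks["wm"][:, 0, 0] = True
    masks["gm"][:, 1, 0] = True
    masks["csf"][:, 2, 0] = True
    return DWIVolume(data, gtab), masks, (sig_fib, sig_gm, sig_csf)


@pytest.fixture(scope="session")
def calibration60(gtab60):
    return _calibration_volume(gtab60)


@pytest.fixture(scope="session")
def responses60(calibration60, gtab60):
    vol, masks, _ = calibration60
    return csd_mod.estimate_responses(vol, gtab60, masks, lmax=8)
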