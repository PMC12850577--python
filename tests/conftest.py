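import numpy as np
import pytest
from scipy import ndimage

from qsmhead import forward, phantom


@pytest.fixture(scope="session")
def head48():
    """Small head phantom with a skull-base GTV."""
    ph = phantom.build_head_phantom((48, 48, 48), (1.0, 1.0, 1.0), seed=7)
    return phantom.insert_gtv(ph, (24, 24, 15), 4.0, 0.3)


@pytest.fixture(scope="session")
def kernel48():
    return forward.padded_kernel_for((48, 48, 48), (1.0, 1.0, 1.0),
                                     (0.0, 0.0, 1.0), pad_factor=2.0)


@pytest.fixture(scope="session")
def acq_params():
    return forward.AcquisitionParams(voxel_size=(1.0, 1.0, 1.0))


@pytest.fixture(scope="session")
def sim48(head48, acq_params):
    """Noiseless 4-echo simulation of the small head phantom."""
    series, true_phase, field = forward.simulate_multiecho_signal(
        head48.chi, acq_params, seed=1, labels=head48.labels,
        structure_table=head48.structure_table)
    return {"series": series, "true_phase": true_phase, "field": field,
            "phantom": head48}


@pytest.fixture(scope="session")
def split_fields48(head48, kernel48):
    """Total/background/local decomposition on the small phantom."""
    chi_s = ndimage.gaussian_filter(head48.chi, 0.7)
    roi = head48.brain_mask()
    bt, bb, bl = forward.split_total_background_local(chi_s, roi, kernel48)
    return {"total": bt, "background": bb, "local": bl, "roi": roi,
            "gtv": head48.mask("GTV"), "chi_smooth": chi_s}
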