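import numpy as np
import pytest

from pathoct.calibration import ideal_calibration
from pathoct.phantom_sim import Phantom, Reflector, simulate_fringe
from pathoct.recon import reconstruct_ascan
from pathoct.system_model import SpectrometerModel, SystemSpec, uniform_k_grid


@pytest.fixture(scope="session")
def clean_spec() -> SystemSpec:
    """Source-limited system: no blur, no pixel integration, no read noise.

    Isolates the source spectrum so PSF measurements can be compared with
    the Gaussian closed form; the roll-off mechanisms are exercised by the
    default spec instead.
    """
    return SystemSpec(
        spectrometer=SpectrometerModel(
            spectral_blur_fwhm_nm=0.0,
            pixel_integration=False,
            read_noise_counts=0.0,
        )
    )


@pytest.fixture(scope="session")
def full_spec() -> SystemSpec:
    """The default system with all roll-off and noise mechanisms on."""
    return SystemSpec()


@pytest.fixture(scope="session")
def uniform_k_spec() -> SystemSpec:
    """A spectrometer whose pixel map is already uniform in wavenumber
    (the k-resampling step becomes the identity)."""
    lam = np.sort(2 * np.pi / uniform_k_grid(SpectrometerModel()))
    return SystemSpec(
        spectrometer=SpectrometerModel(
            wavelength_map_nm=tuple(lam),
            spectral_blur_fwhm_nm=0.0,
            pixel_integration=False,
            read_noise_counts=0.0,
        )
    )


@pytest.fixture(scope="session")
def small_spec() -> SystemSpec:
    """Scaled-down raster for tile/volume tests."""
    return SystemSpec(a_lines_per_bscan=8, bscans_per_volume=4)


def mirror_ascan(spec: SystemSpec, depth_um: float, reflectivity: float = 0.05,
                 window: str = "rect", cal=None):
    """Simulate and reconstruct a single noiseless mirror."""
    phantom = Phantom(reflectors=(Reflector(depth_um=depth_um, reflectivity=reflectivity),))
    fringe, _ = simulate_fringe(phantom, spec, noiseless=True)
    if cal is None:
        cal = ideal_calibration(spec)
    return reconstruct_ascan(fringe, cal, spec, window)
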