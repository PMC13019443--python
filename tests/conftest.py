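import numpy as np
import pytest

from sorsbone import (
    AcquisitionMeta,
    GeneratorConfig,
    Spectrum,
    WavenumberAxis,
    generate_cohort,
)


@pytest.fixture(scope="session")
def axis():
    return WavenumberAxis.default()


@pytest.fixture
def gaussian_spectrum(axis):
    """Factory: sum of Gaussian peaks on the default axis."""

    def make(peaks, meta=None, background=None):
        x = axis.values
        y = np.zeros_like(x)
        for center, sigma, amp in peaks:
            y += amp * np.exp(-0.5 * ((x - center) / sigma) ** 2)
        if background is not None:
            y += background(x)
        return Spectrum(axis, y, meta or AcquisitionMeta(subject_id="s"))

    return make


@pytest.fixture(scope="session")
def default_cohort():
    """The default seeded cohort: 6/4/11 subjects, 3 sites each."""
    return generate_cohort((6, 4, 11), GeneratorConfig(), seed=17)


@pytest.fixture(scope="session")
def default_reconstruction(default_cohort):
    """LOSO reconstruction of the default cohort at 10 components."""
    from sorsbone import loso_reconstruct

    data, _, _ = default_cohort
    return loso_reconstruct(data, A=10)


@pytest.fixture(scope="session")
def noiseless_config():
    return GeneratorConfig(
        noise_sd=0.0, baseline_scale=0.0,
        subject_jitter_sigma=0.0, site_jitter_sigma=0.0,
    )
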