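import numpy as np
import pytest

from mdcl import phantom


@pytest.fixture(scope="session")
def clean_phantom():
    """Noise-free, confounder-free phantom: labels recoverable by threshold."""
    spec = phantom.PhantomSpec(noise_sd=0.0, n_confounders=0, seed=3)
    return phantom.make_phantom(spec)


@pytest.fixture(scope="session")
def noisy_phantom():
    """Default-condition phantom (noise + confounders)."""
    spec = phantom.PhantomSpec(seed=5)
    return phantom.make_phantom(spec)


@pytest.fixture(scope="session")
def fg_patch(clean_phantom):
    """A 32x32x8 patch centred on foreground, with its labels."""
    v, m = clean_phantom
    c = np.argwhere(m.labels).mean(axis=0).astype(int)
    x0 = int(np.clip(c[0] - 16, 0, v.shape[0] - 32))
    y0 = int(np.clip(c[1] - 16, 0, v.shape[1] - 32))
    z0 = int(np.clip(c[2] - 4, 0, v.shape[2] - 8))
    img = v.intensities[x0:x0 + 32, y0:y0 + 32, z0:z0 + 8].astype(np.float32)
    lab = m.labels[x0:x0 + 32, y0:y0 + 32, z0:z0 + 8].astype(np.int64)
    assert lab.sum() > 50, "fixture must contain foreground"
    return img, lab


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small cohort for orchestration tests (not for accuracy claims)."""
    spec = phantom.PhantomSpec(noise_sd=0.0, n_confounders=1, seed=0)
    return phantom.make_cohort(1, 1, 1, 1, spec, seed=7)
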