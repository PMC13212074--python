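import numpy as np
import pytest

import nirsgait as ng
from nirsgait.simulate import NoiseSpec


ZERO_NOISE = NoiseSpec(
    cardiac=(1.0, 0.0), respiratory=(0.3, 0.0), mayer=(0.1, 0.0),
    drift_slope=0.0, drift_rw=0.0, white=0.0, background=0.0, hhb_white=0.0,
)


@pytest.fixture(scope="session")
def montage():
    return ng.build_default_montage()


@pytest.fixture(scope="session")
def paradigm():
    return ng.default_paradigm()


@pytest.fixture(scope="session")
def noise_free_spec():
    """Paper-like activation effects, but zero noise and no artifacts."""
    from dataclasses import replace

    spec = ng.published_cohort(seed=0, n_per_group=2)
    return replace(spec, noise=ZERO_NOISE, artifact_rate=0.0, fc_subject_sd={})


@pytest.fixture(scope="session")
def clean_recording(noise_free_spec):
    """Deterministic noise-free HC session (fixed subject amplitudes)."""
    amps = {(roi, cond): noise_free_spec.activation_effects[("HC", roi, cond)][0]
            for roi in ("PFC", "PMC", "M1", "S1", "TLC")
            for cond in ("freeze_walk", "normal_walk")}
    return ng.simulate_session(noise_free_spec, "HC01", "HC", 7, subject_amplitudes=amps)


@pytest.fixture(scope="session")
def noisy_recording():
    spec = ng.published_cohort(seed=0, n_per_group=2)
    return ng.simulate_session(spec, "PD01", "PD_FOG", 11)


@pytest.fixture(scope="session")
def preprocessed(noisy_recording):
    hb, qc = ng.preprocess_recording(noisy_recording)
    return hb


@pytest.fixture(scope="session")
def small_cohort():
    """Tiny published cohort (3 per group) for pipeline-level tests."""
    spec = ng.published_cohort(seed=5, n_per_group=3)
    recordings, gait = ng.simulate_cohort(spec)
    return spec, recordings, gait


def hb_from_array(hbo: np.ndarray, fs: float = 11.0, qc_mask=None) -> ng.HbSeries:
    """Wrap a (48, T) HbO2 array as an HbSeries (HHb = -HbO2/3)."""
    data = np.stack([hbo, -hbo / 3.0], axis=1)
    if qc_mask is None:
        qc_mask = np.ones(48, dtype=bool)
    return ng.HbSeries(data=data, fs=fs, qc_mask=qc_mask, subject_id="T01", group="HC")
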