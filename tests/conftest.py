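import numpy as np
import pytest

from chronossa import ActigraphySeries, CohortSpec, generate_subject


def make_series(counts, epoch=1.0, start=0.0, subject="s", group="g"):
    return ActigraphySeries(
        subject_id=subject,
        group=group,
        start_clock=start,
        epoch_minutes=epoch,
        counts=np.asarray(counts, dtype=float),
    )


@pytest.fixture
def cosine_series():
    """Noise-free 7-day circadian cosine at 1-min epochs (peak 15:28)."""
    t = np.arange(7 * 1440.0)
    counts = 216.0 + 178.0 * np.cos(2 * np.pi * (t - 928.0) / 1440.0)
    return make_series(counts)


@pytest.fixture
def clean_subject():
    """Generated subject with no stochastic components (exact cosine)."""
    spec = CohortSpec(
        mesor_sd=0.0,
        amplitude_day_cv=0.0,
        acrophase_day_sd=0.0,
        noise_scale=0.0,
        seed=1,
    )
    return generate_subject(spec, 0)


@pytest.fixture
def fast_subject():
    """Default-condition subject at 5-min epochs (cheap SSA: L=288)."""
    spec = CohortSpec(epoch_minutes=5.0, seed=7)
    return generate_subject(spec, 0)
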