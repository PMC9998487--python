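import pytest

from oryxhr.model import fit_additive_model, standard_ladder
from oryxhr.pipeline import synthetic_hourly_frame
from oryxhr.synth import SeriesSynthParams


@pytest.fixture(scope="session")
def full_frame_truth():
    """Default 6-animal x 120-day synthetic series carried to the
    hourly modeling frame, with its truth ledger."""
    return synthetic_hourly_frame(SeriesSynthParams(seed=0))


@pytest.fixture(scope="session")
def full_fit(full_frame_truth):
    """Full-interaction additive model fitted to the default series."""
    frame, _ = full_frame_truth
    return fit_additive_model(frame, standard_ladder()[-1])
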