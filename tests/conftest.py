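from types import SimpleNamespace

import numpy as np
import pytest


class TrackEnsemble:
    """Minimal trajectory stand-in (synthetic): times plus named variable
    arrays of shape (n_times, n_cones), mimicking EnsembleTrajectory."""

    def __init__(self, times, config=None, **arrays):
        self.times = np.asarray(times, dtype=float)
        self._arrays = {k: np.asarray(v, dtype=float) for k, v in arrays.items()}
        self.config = config or SimpleNamespace(
            v0_um_per_h=30.0, spatial_period_d_um=3.0
        )

    def values(self, name):
        return self._arrays[name]


@pytest.fixture
def track_ensemble_factory():
    return TrackEnsemble
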