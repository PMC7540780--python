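import numpy as np
import pandas as pd
import pytest

from petrelniche import Track, default_config, simulate_tracks


def make_track(
    lonlats,
    start="2016-10-01",
    freq_min=60,
    nest=(0.0, 0.0),
    individual_id="toy",
    species="NGP",
    sex="female",
    year=2016,
):
    """Toy track from a list of (lon, lat) at a fixed sampling interval."""
    ll = np.asarray(lonlats, dtype=float)
    ts = pd.date_range(start, periods=len(ll), freq=pd.Timedelta(minutes=freq_min))
    pts = pd.DataFrame({"timestamp": ts, "lon": ll[:, 0], "lat": ll[:, 1]})
    return Track(individual_id, species, sex, year, nest, pts)


@pytest.fixture()
def toy_track_factory():
    return make_track


def loo_studentized_oracle(x, y):
    """Externally studentized residuals by brute-force leave-one-out refits."""
    import math

    n = len(x)
    out = np.empty(n)
    X = np.column_stack([np.ones(n), x])
    for i in range(n):
        keep = np.arange(n) != i
        beta, *_ = np.linalg.lstsq(X[keep], y[keep], rcond=None)
        resid = y[keep] - X[keep] @ beta
        s2 = resid @ resid / (keep.sum() - 2)
        xi = X[i]
        pred_var = s2 * (1.0 + xi @ np.linalg.inv(X[keep].T @ X[keep]) @ xi)
        out[i] = (y[i] - xi @ beta) / math.sqrt(pred_var)
    return out


@pytest.fixture(scope="session")
def default_tracks():
    """One small default simulation shared across read-only tests."""
    cfg = default_config(n_individuals_per_group=6, seed=7, window_start="2016-10-01", window_end="2016-10-07")
    return cfg, simulate_tracks(cfg)
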