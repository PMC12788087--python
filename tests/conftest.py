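"""Shared fixtures and independent oracles for the test suite."""

import numpy as np
import pytest

from cmjkin.events import EventConfig


# ---------------------------------------------------------------------------
# independent brute-force oracles (kept deliberately naive)
# ---------------------------------------------------------------------------

def oracle_detect(z, cfg: EventConfig | None = None):
    """Direct linear scan over all samples checking the threshold
    predicates — the reference for the event detector.

    Returns (i_onset, i_min, i_takeoff, i_apex) or None when the signal
    has no valid countermovement.
    """
    cfg = cfg or EventConfig()
    z = np.asarray(z, float)
    n = len(z)
    if n < 3:
        return None
    # first global minimum
    i_min, z_min = 0, z[0]
    for i in range(n):
        if z[i] < z_min:
            i_min, z_min = i, z[i]
    if z_min >= 0 or i_min in (0, n - 1):
        return None
    # apex: last-scan argmax after the trough (first index on ties)
    i_apex, z_apex = i_min, z[i_min]
    for i in range(i_min, n):
        if z[i] > z_apex:
            i_apex, z_apex = i, z[i]
    if z_apex <= 0:
        return None
    # onset: scan backward from the trough while still below threshold
    thr_on = cfg.onset_fraction * z_min
    i_onset = i_min
    while i_onset > 0 and z[i_onset - 1] <= thr_on:
        i_onset -= 1
    if i_onset == 0:
        return None
    # take-off: first sample after trough at/above its threshold
    rng = z_apex - z_min
    if cfg.takeoff_rule == "literal":
        thr_to = z_min + cfg.takeoff_fraction * rng
    else:
        thr_to = z_apex - cfg.takeoff_fraction * rng
    i_takeoff = None
    for i in range(i_min + 1, i_apex + 1):
        if z[i] >= thr_to:
            i_takeoff = i
            break
    if i_takeoff is None:
        return None
    return i_onset, i_min, i_takeoff, i_apex


def oracle_icc31(x):
    """Two-way ANOVA by explicit sums of squares, then the consistency
    ICC formula — the reference for ``icc_3_1``."""
    x = np.asarray(x, float)
    n, k = x.shape
    grand = sum(x[i, j] for i in range(n) for j in range(k)) / (n * k)
    ss_total = sum((x[i, j] - grand) ** 2
                   for i in range(n) for j in range(k))
    ss_subj = k * sum((sum(x[i, :]) / k - grand) ** 2 for i in range(n))
    ss_meth = n * sum((sum(x[:, j]) / n - grand) ** 2 for j in range(k))
    ss_err = ss_total - ss_subj - ss_meth
    ms_s = ss_subj / (n - 1)
    ms_e = ss_err / ((n - 1) * (k - 1))
    return (ms_s - ms_e) / (ms_s + (k - 1) * ms_e)


def random_piecewise_linear_jump(rng, n_min=120, n_max=400):
    """Random jump-shaped piecewise-linear signal for oracle comparison.

    Quiet → linear descent to a random negative trough → linear ascent
    to a random positive apex → short linear tail. Small per-sample
    noise keeps thresholds generic (ties unlikely).
    """
    n_quiet = int(rng.integers(10, 60))
    n_down = int(rng.integers(20, 120))
    n_up = int(rng.integers(20, 120))
    n_tail = int(rng.integers(5, 40))
    depth = float(rng.uniform(0.05, 0.6))
    apex = float(rng.uniform(0.05, 0.8))
    z = np.concatenate([
        np.zeros(n_quiet),
        np.linspace(0, -depth, n_down, endpoint=False),
        np.linspace(-depth, apex, n_up, endpoint=False),
        np.linspace(apex, apex * 0.4, n_tail),
    ])
    z = z + rng.normal(0, 1e-4, len(z))
    return z


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def vee_signal():
    """The piecewise-linear reference jump: 0 → −0.40 m over 0.5 s,
    then up to +0.40 m over 0.8 s, sampled at 1000 Hz."""
    rate = 1000.0
    t = np.arange(0, int(1.3 * rate) + 1) / rate
    z = np.where(t <= 0.5, -0.8 * t, -0.4 + (t - 0.5) * 1.0)
    return t, z
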