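"""Trajectory readouts: oscillation statistics, fate calls, proportions.

Fates are assigned from two scalars per cell computed over a late analysis
window (default 3200-3600 min): the window-mean Ptf1a and the Hes1
oscillation amplitude (mean of peak values minus mean of trough values).
A cell is a pro-acinar cell (PAC) when its mean Ptf1a exceeds ``theta_p``;
otherwise it is a bipotent progenitor (BP) when the Hes1 amplitude exceeds
``theta_a_high``, and an undifferentiated multipotent progenitor (MPC) with
intermediate amplitude otherwise.  The default thresholds were placed once
in the wide gaps of the pooled log-scale distributions of the two readouts
from a reference wild-type tissue run and then frozen, so every condition
is compared with the same classifier.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from notchsim.geometry import MESENCHYMAL

__all__ = [
    "OscStats",
    "FateThresholds",
    "FateTable",
    "DEFAULT_THRESHOLDS_3D",
    "DEFAULT_THRESHOLDS_TWOCELL",
    "oscillation_stats",
    "classify_fate",
    "fate_proportions",
    "normalize_align",
    "phase_relation",
]

FATES = ("MPC", "PAC", "BP")

# peak detector settings: minimum prominence as a fraction of the trace's
# range in the window, and minimum peak separation in minutes (oscillation
# periods are ~90-160 min, so 30 min separates genuine cycles)
PEAK_PROMINENCE_FRACTION = 0.05
PEAK_MIN_SEPARATION_MIN = 30.0


@dataclass(frozen=True)
class OscStats:
    """Peak/trough summary of one oscillatory trace within a window.

    ``amplitude`` is mean(peaks) - mean(troughs) and is 0 for flat traces;
    ``period`` is the mean adjacent-peak interval, NaN when fewer than two
    peaks exist.
    """

    peak_times: np.ndarray
    peak_values: np.ndarray
    trough_times: np.ndarray
    trough_values: np.ndarray
    amplitude: float
    period: float

    @property
    def oscillatory(self) -> bool:
        return np.isfinite(self.period)


@dataclass(frozen=True)
class FateThresholds:
    """Classifier thresholds: Ptf1a cut for PAC, amplitude band for BP/MPC."""

    theta_p: float
    theta_a_low: float
    theta_a_high: float

    def __post_init__(self):
        if not self.theta_a_low < self.theta_a_high:
            raise ValueError("theta_a_low must be < theta_a_high")
        if min(self.theta_p, self.theta_a_low) < 0:
            raise ValueError("thresholds must be >= 0")


# Frozen defaults from the widest-gap procedure (see fit_thresholds) on a
# reference wild-type run of each model; all conditions are classified with
# the same numbers so comparisons are threshold-consistent.
DEFAULT_THRESHOLDS_3D = FateThresholds(theta_p=1.80, theta_a_low=0.53, theta_a_high=3.08)
DEFAULT_THRESHOLDS_TWOCELL = FateThresholds(theta_p=1.06, theta_a_low=0.30, theta_a_high=3.01)


def _widest_log_gap(values: np.ndarray) -> float:
    """Geometric midpoint of the widest gap of a positive sample in log scale."""
    v = np.sort(values[values > 0])
    if len(v) < 2:
        raise ValueError("need at least two positive values")
    gaps = np.diff(np.log(v))
    k = int(np.argmax(gaps))
    return float(np.sqrt(v[k] * v[k + 1]))


def fit_thresholds(mean_ptf1a: np.ndarray, hes1_amplitude: np.ndarray) -> FateThresholds:
    """Place classifier thresholds in the widest log-scale gaps of a
    reference run's pooled readouts.

    ``theta_p`` splits the bimodal mean-Ptf1a distribution; ``theta_a_high``
    splits the Hes1 amplitudes of the remaining (non-PAC) cells into the
    oscillatory BP mode and the intermediate MPC mode; ``theta_a_low``
    separates the MPC band from the near-flat PAC amplitudes.  The package
    defaults were produced by this function on a wild-type reference run
    and then frozen.
    """
    mean_ptf1a = np.asarray(mean_ptf1a, float)
    hes1_amplitude = np.asarray(hes1_amplitude, float)
    theta_p = _widest_log_gap(mean_ptf1a)
    non_pac = np.sort(hes1_amplitude[mean_ptf1a <= theta_p])
    non_pac = non_pac[non_pac > 0]
    gaps = np.diff(np.log(non_pac))
    if len(gaps) < 2:
        raise ValueError("too few non-PAC cells to place the amplitude band")
    top_two = np.sort(np.argsort(gaps)[-2:])
    lo_k, hi_k = int(top_two[0]), int(top_two[1])
    theta_a_low = float(np.sqrt(non_pac[lo_k] * non_pac[lo_k + 1]))
    theta_a_high = float(np.sqrt(non_pac[hi_k] * non_pac[hi_k + 1]))
    if lo_k == hi_k:  # pragma: no cover - argsort always yields two indices
        raise ValueError("degenerate amplitude distribution")
    return FateThresholds(theta_p=theta_p, theta_a_low=theta_a_low, theta_a_high=theta_a_high)


@dataclass
class FateTable:
    """Per-cell readouts plus population proportions for one run."""

    per_cell: pd.DataFrame
    proportions: dict
    counts: dict
    thresholds: FateThresholds
    window: tuple

    @property
    def n_cells(self) -> int:
        return len(self.per_cell)


def oscillation_stats(t: np.ndarray, x: np.ndarray, window: tuple) -> OscStats:
    """Peaks, troughs, amplitude and period of a trace within a window."""
    t = np.asarray(t, float)
    x = np.asarray(x, float)
    lo, hi = window
    mask = (t >= lo - 1e-9) & (t <= hi + 1e-9)
    if not mask.any():
        raise ValueError("empty analysis window")
    tw, xw = t[mask], x[mask]
    if len(tw) < 10:
        raise ValueError("need at least 10 samples in the window")
    rng = float(xw.max() - xw.min())
    if rng <= 0:
        empty = np.array([])
        return OscStats(empty, empty, empty, empty, amplitude=0.0, period=np.nan)
    dt = float(np.median(np.diff(tw)))
    distance = max(1, int(round(PEAK_MIN_SEPARATION_MIN / dt)))
    prom = PEAK_PROMINENCE_FRACTION * rng
    pk, _ = find_peaks(xw, prominence=prom, distance=distance)
    tr, _ = find_peaks(-xw, prominence=prom, distance=distance)
    if pk.size == 0 or tr.size == 0:
        empty = np.array([])
        return OscStats(empty, empty, empty, empty, amplitude=0.0, period=np.nan)
    amplitude = float(xw[pk].mean() - xw[tr].mean())
    period = float(np.diff(tw[pk]).mean()) if pk.size >= 2 else np.nan
    return OscStats(
        peak_times=tw[pk],
        peak_values=xw[pk],
        trough_times=tw[tr],
        trough_values=xw[tr],
        amplitude=amplitude,
        period=period,
    )


def classify_fate(
    mean_ptf1a: float, hes1_amplitude: float, thresholds: FateThresholds
) -> str:
    """PAC for high Ptf1a; otherwise BP above the high-amplitude cut, MPC below."""
    if mean_ptf1a < 0 or hes1_amplitude < 0:
        raise ValueError("inputs must be >= 0")
    if mean_ptf1a > thresholds.theta_p:
        return "PAC"
    if hes1_amplitude > thresholds.theta_a_high:
        return "BP"
    return "MPC"


def fate_proportions(trajset, thresholds: FateThresholds | None = None, window=None):
    """Per-cell fate table and population proportions for one run.

    Marks each cell as surface (has >= 1 mesenchymal graph neighbor) or
    interior, computes window-mean Ptf1a and Hes1 amplitude/period, and
    classifies every cell.
    """
    if thresholds is None:
        thresholds = (
            DEFAULT_THRESHOLDS_TWOCELL
            if trajset.config.preset == "table1_twocell"
            else DEFAULT_THRESHOLDS_3D
        )
    if window is None:
        window = trajset.config.window
    lo, hi = window
    t = trajset.t
    if lo < t[0] - 1e-9 or hi > t[-1] + 1e-9:
        raise ValueError("window outside the simulated range")
    H = trajset.var("H")
    P = trajset.var("P")
    mask = (t >= lo - 1e-9) & (t <= hi + 1e-9)

    graph = trajset.graph
    rows = []
    for i, cid in enumerate(trajset.cell_ids):
        stats = oscillation_stats(t, H[:, i], window)
        meanp = float(P[mask, i].mean())
        fate = classify_fate(meanp, stats.amplitude, thresholds)
        surface = False
        if graph is not None and graph.cell_class is not None:
            surface = any(
                graph.cell_class[j] == MESENCHYMAL for j in graph.neighbors[cid]
            )
        rows.append(
            dict(
                cell_id=int(cid),
                surface=bool(surface),
                mean_ptf1a=meanp,
                hes1_amplitude=stats.amplitude,
                hes1_period=stats.period,
                fate=fate,
            )
        )
    df = pd.DataFrame(rows)
    counts = {f: int((df["fate"] == f).sum()) for f in FATES}
    n = len(df)
    proportions = {f: counts[f] / n for f in FATES}
    return FateTable(
        per_cell=df,
        proportions=proportions,
        counts=counts,
        thresholds=thresholds,
        window=(float(lo), float(hi)),
    )


def normalize_align(traces, t: np.ndarray | None = None, window=None):
    """Min-max normalize traces and align them on their first peaks.

    Each trace is mapped to [0, 1] by (x - min)/(max - min); traces are
    re-indexed in time so their first detected peaks coincide.  Constant
    traces and traces without a detectable peak are excluded and flagged.

    Returns ``(normalized, offsets, excluded)`` where ``normalized`` is a
    list of (shifted_time, values) pairs, ``offsets`` the per-trace time
    shift subtracted (NaN for excluded traces), and ``excluded`` the list
    of excluded trace indices.
    """
    traces = [np.asarray(x, float) for x in traces]
    if t is None:
        t = np.arange(len(traces[0]), dtype=float)
    t = np.asarray(t, float)
    if window is None:
        window = (float(t[0]), float(t[-1]))

    normalized, offsets, excluded = [], [], []
    for i, x in enumerate(traces):
        rng = x.max() - x.min()
        if rng <= 0:
            offsets.append(np.nan)
            excluded.append(i)
            continue
        xn = (x - x.min()) / rng
        stats = oscillation_stats(t, x, window)
        if stats.peak_times.size == 0:
            offsets.append(np.nan)
            excluded.append(i)
            continue
        t0 = float(stats.peak_times[0])
        normalized.append((t - t0, xn))
        offsets.append(t0)
    return normalized, np.array(offsets), excluded


def phase_relation(
    t: np.ndarray, trace_a: np.ndarray, trace_b: np.ndarray, window: tuple
) -> float:
    """Zero-lag correlation of the mean-subtracted traces in the window.

    Scores near -1 indicate anti-phase oscillation, near +1 in-phase.
    Raises when either trace is flat in the window (phase undefined).
    """
    t = np.asarray(t, float)
    mask = (t >= window[0] - 1e-9) & (t <= window[1] + 1e-9)
    a = np.asarray(trace_a, float)[mask]
    b = np.asarray(trace_b, float)[mask]
    a = a - a.mean()
    b = b - b.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("flat trace in window: phase score undefined")
    return float(a @ b / (na * nb))
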