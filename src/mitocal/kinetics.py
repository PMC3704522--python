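"""Calcium-transient kinetics from fluorescence traces.

Extracts the standard caffeine-response readouts from a single-cell Fluo-4
trace with a known stimulus-application time: pre-stimulus baseline, onset
latency ("caffeine response time"), time to peak, amplitude, maximal rise
rate (ΔF/ΔT) and the 25/50/90 % clearance times with right-censoring when
the recording ends before the trace has recovered.

Conventions (documented because the readouts are only mutually consistent
this way):

* ``response_time`` is measured from stimulus application to detected
  onset; ``time_to_peak`` is measured from the detected onset to the peak
  — two separate legs, not both from application.
* Clearance is referenced to the pre-stimulus baseline and the measured
  amplitude: ``t_q`` is the first post-peak time at which fluorescence has
  lost a fraction ``q`` of the rise, linearly interpolated between samples.
* Amplitudes stay in raw fau; no ΔF/F0 normalisation is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np
import pandas as pd

__all__ = [
    "FluorescenceTrace",
    "KineticsConfig",
    "TransientMetrics",
    "NoResponse",
    "estimate_baseline",
    "detect_onset",
    "peak_metrics",
    "max_rate",
    "clearance_times",
    "analyze_transient",
    "analyze_batch",
]

_CLEARANCE_FRACTIONS = (0.25, 0.50, 0.90)


class NoResponse(Exception):
    """Raised internally when no onset is detected; callers normally see a
    fully-flagged :class:`TransientMetrics` instead."""


@dataclass(frozen=True)
class FluorescenceTrace:
    """Uniformly sampled fluorescence vs time with the stimulus time."""

    time: np.ndarray  # s, strictly increasing uniform grid
    fluorescence: np.ndarray  # fau
    t_app: float  # s

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        f = np.asarray(self.fluorescence, dtype=float)
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "fluorescence", f)
        if t.ndim != 1 or f.shape != t.shape:
            raise ValueError("time and fluorescence must be 1-D of equal length")
        if t.size < 20:
            raise ValueError("trace must have at least 20 samples")
        steps = np.diff(t)
        if not (steps > 0).all():
            raise ValueError("time must be strictly increasing")
        dt = steps.mean()
        if np.abs(steps - dt).max() > 1e-6 * max(dt, 1.0):
            raise ValueError("time grid must be uniform")
        if not (t[0] <= self.t_app < t[-1]):
            raise ValueError("t_app must fall within the recorded interval")

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0])

    @property
    def n(self) -> int:
        return int(self.time.size)


@dataclass(frozen=True)
class KineticsConfig:
    """Tunables of the metric extraction.

    ``onset_abs_floor`` keeps onset detection meaningful on noiseless
    traces, where the baseline SD (and hence ``onset_k * sd``) is zero.
    """

    baseline_window: float = 20.0  # s before t_app
    onset_k: float = 3.0  # threshold, multiples of baseline SD
    onset_min_samples: int = 3  # consecutive supra-threshold samples
    onset_abs_floor: float = 1.0  # fau
    smooth_window: int = 5  # odd, samples; derivative smoothing

    def __post_init__(self) -> None:
        if self.baseline_window <= 0:
            raise ValueError("baseline_window must be > 0")
        if self.onset_k <= 0:
            raise ValueError("onset_k must be > 0")
        if self.smooth_window < 1 or self.smooth_window % 2 == 0:
            raise ValueError("smooth_window must be odd and >= 1")
        if self.onset_min_samples < 1:
            raise ValueError("onset_min_samples must be >= 1")


@dataclass
class TransientMetrics:
    """Per-trace kinetic summary; NaN + ``no_response`` when nothing fired."""

    baseline_f0: float
    baseline_sd: float
    response_time: float = np.nan  # s after t_app
    time_to_peak: float = np.nan  # s, onset -> peak
    amplitude: float = np.nan  # fau
    max_rate: float = np.nan  # fau/s
    t25: float = np.nan  # s after peak
    t50: float = np.nan
    t90: float = np.nan
    t25_censored: bool = False
    t50_censored: bool = False
    t90_censored: bool = False
    t_peak_abs: float = np.nan  # s, absolute peak time
    no_response: bool = False
    low_confidence_rate: bool = False

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def estimate_baseline(
    trace: FluorescenceTrace, config: KineticsConfig = KineticsConfig()
) -> tuple[float, float]:
    """Mean and sample SD of fluorescence over the pre-stimulus window."""
    sel = (trace.time >= trace.t_app - config.baseline_window) & (
        trace.time < trace.t_app
    )
    if sel.sum() < 5:
        raise ValueError(
            f"only {int(sel.sum())} samples in the {config.baseline_window} s "
            "pre-stimulus window; need at least 5"
        )
    f = trace.fluorescence[sel]
    return float(f.mean()), float(f.std(ddof=1))


def detect_onset(
    trace: FluorescenceTrace,
    baseline: tuple[float, float],
    config: KineticsConfig = KineticsConfig(),
) -> float:
    """Onset latency (s after ``t_app``) by sustained threshold crossing.

    The onset is the first time at or after ``t_app`` where fluorescence
    exceeds ``baseline + max(onset_k * sd, onset_abs_floor)`` for
    ``onset_min_samples`` consecutive samples.  Raises :class:`NoResponse`
    when the trace never satisfies the rule.
    """
    f0, sd = baseline
    thr = f0 + max(config.onset_k * sd, config.onset_abs_floor)
    idx0 = int(np.searchsorted(trace.time, trace.t_app))
    above = trace.fluorescence[idx0:] > thr
    k = config.onset_min_samples
    if above.size >= k:
        # run of k consecutive True values starting at i
        run = np.ones(above.size - k + 1, dtype=bool)
        for j in range(k):
            run &= above[j : above.size - k + 1 + j]
        hits = np.flatnonzero(run)
        if hits.size:
            return float(trace.time[idx0 + hits[0]] - trace.t_app)
    raise NoResponse("fluorescence never exceeded the onset threshold")


def peak_metrics(
    trace: FluorescenceTrace, baseline: tuple[float, float], onset: float
) -> tuple[float, float, int]:
    """Amplitude (fau) and time to peak (s from onset); ties -> earliest.

    Also returns the peak sample index for downstream clearance timing.
    """
    t_on = trace.t_app + onset
    sel = trace.time >= t_on
    f_post = trace.fluorescence[sel]
    i_rel = int(np.argmax(f_post))  # argmax takes the earliest maximum
    i_peak = int(np.flatnonzero(sel)[i_rel])
    amplitude = float(trace.fluorescence[i_peak] - baseline[0])
    time_to_peak = float(trace.time[i_peak] - t_on)
    return amplitude, time_to_peak, i_peak


def _moving_average(f: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return f.astype(float)
    kernel = np.ones(window) / window
    pad = window // 2
    padded = np.pad(f, pad, mode="edge")
    return np.convolve(padded, kernel, mode="valid")


def max_rate(
    trace: FluorescenceTrace,
    onset: float,
    i_peak: int,
    config: KineticsConfig = KineticsConfig(),
) -> tuple[float, bool]:
    """Maximal first derivative ΔF/ΔT (fau/s) over the rising phase.

    Fluorescence is smoothed with a centred moving average of
    ``smooth_window`` samples and differentiated by central differences;
    the maximum is taken over [onset, peak].  When fewer than 3 samples
    separate onset and peak the rate falls back to the single available
    difference and is flagged low-confidence.
    """
    smooth = _moving_average(trace.fluorescence, config.smooth_window)
    i_on = int(np.searchsorted(trace.time, trace.t_app + onset))
    lo = max(i_on, 1)
    hi = min(i_peak, trace.n - 2)
    if hi < lo:  # degenerate: onset and peak adjacent or at the edge
        i = min(max(i_on, 0), trace.n - 2)
        rate = (smooth[i + 1] - smooth[i]) / trace.dt
        return float(rate), True
    deriv = (smooth[lo + 1 : hi + 2] - smooth[lo - 1 : hi]) / (2.0 * trace.dt)
    low_conf = (hi - lo + 1) < 3
    return float(deriv.max()), low_conf


def clearance_times(
    trace: FluorescenceTrace,
    baseline: tuple[float, float],
    amplitude: float,
    i_peak: int,
) -> dict[str, tuple[float, bool]]:
    """t25/t50/t90: time from peak until 25/50/90 % of the rise has cleared.

    For each fraction ``q`` the crossing of ``baseline + (1 - q) *
    amplitude`` is located after the peak and refined by linear
    interpolation between the bracketing samples.  If the recording ends
    first the value is the remaining record length with a censored flag.
    """
    if not amplitude > 0:
        raise ValueError("clearance requires a positive amplitude")
    f0 = baseline[0]
    t = trace.time
    f = trace.fluorescence
    t_peak = t[i_peak]
    out: dict[str, tuple[float, bool]] = {}
    for q in _CLEARANCE_FRACTIONS:
        level = f0 + (1.0 - q) * amplitude
        below = np.flatnonzero(f[i_peak:] <= level)
        key = f"t{int(q * 100)}"
        if below.size == 0:
            out[key] = (float(t[-1] - t_peak), True)
            continue
        j = i_peak + int(below[0])
        if j == i_peak:
            out[key] = (0.0, False)
            continue
        # interpolate between the bracketing samples j-1 (above) and j
        f1, f2 = f[j - 1], f[j]
        frac = (f1 - level) / (f1 - f2) if f1 != f2 else 1.0
        t_cross = t[j - 1] + frac * (t[j] - t[j - 1])
        out[key] = (float(t_cross - t_peak), False)
    return out


def analyze_transient(
    trace: FluorescenceTrace, config: KineticsConfig = KineticsConfig()
) -> TransientMetrics:
    """Full per-trace summary: baseline → onset → peak → rate → clearance.

    A trace with no detectable response yields a record with
    ``no_response=True`` and NaN metrics rather than an error.
    """
    f0, sd = estimate_baseline(trace, config)
    try:
        onset = detect_onset(trace, (f0, sd), config)
    except NoResponse:
        return TransientMetrics(baseline_f0=f0, baseline_sd=sd, no_response=True)
    amplitude, ttp, i_peak = peak_metrics(trace, (f0, sd), onset)
    rate, low_conf = max_rate(trace, onset, i_peak, config)
    m = TransientMetrics(
        baseline_f0=f0,
        baseline_sd=sd,
        response_time=onset,
        time_to_peak=ttp,
        amplitude=amplitude,
        max_rate=rate,
        t_peak_abs=float(trace.time[i_peak]),
        low_confidence_rate=low_conf,
    )
    if amplitude > 0:
        cl = clearance_times(trace, (f0, sd), amplitude, i_peak)
        m.t25, m.t25_censored = cl["t25"]
        m.t50, m.t50_censored = cl["t50"]
        m.t90, m.t90_censored = cl["t90"]
    return m


def analyze_batch(
    traces: list[FluorescenceTrace],
    config: KineticsConfig = KineticsConfig(),
    trace_ids: list | None = None,
    groups: list | None = None,
) -> pd.DataFrame:
    """Metrics table for a list of traces, order preserved."""
    rows = []
    for i, tr in enumerate(traces):
        rec = analyze_transient(tr, config).to_dict()
        rec["trace_id"] = trace_ids[i] if trace_ids is not None else i
        if groups is not None:
            rec["group"] = groups[i]
        rows.append(rec)
    df = pd.DataFrame(rows)
    lead = ["trace_id"] + (["group"] if groups is not None else [])
    return df[lead + [c for c in df.columns if c not in lead]]
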