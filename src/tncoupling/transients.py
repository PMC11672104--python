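"""Cardiomyocyte shortening transients: beat features and lusitropy.

Cell-length records (10 s at 1 Hz field stimulation) are segmented
into beats; each beat yields the contractile amplitude as a percent of
resting length (%L0), the time from contraction onset to 90% of peak
shortening (ttp90) and the time from the peak to 90% recovery of the
shortening amplitude (ttb90).  The lusitropic response to the
beta-1 agonist dobutamine is the fractional shortening of ttb90,

    lusitropy = 1 - ttb90(+dobutamine) / ttb90(-dobutamine),

positive when relaxation gets faster; cardiomyopathy mutations blunt
it and recoupling small molecules restore it.  Group comparisons use
two-tailed paired t-tests per cell.

Conventions (the instrumentation literature does not fix them): beat
onset is the crossing of 10% of the beat amplitude on the shortening
phase of the 5-sample moving-average smoothed trace; per-cell features
are medians over accepted beats.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "TransientTrace",
    "BeatWindow",
    "BeatFeatures",
    "LusitropyResult",
    "PairedResponse",
    "TransientError",
    "segment_beats",
    "beat_features",
    "trace_features",
    "lusitropy",
    "paired_response",
]

SMOOTH_WINDOW_SAMPLES = 5
ONSET_AMPLITUDE_FRACTION = 0.10


class TransientError(ValueError):
    """Raised for unusable transient traces."""


@dataclass
class TransientTrace:
    time_s: np.ndarray
    cell_length: np.ndarray        # um, or normalized units
    stimulus_rate_hz: float = 1.0
    cell_id: str = "cell"
    treatment: str = "baseline"    # "baseline" or "dobutamine" (x ligand label)

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.cell_length = np.asarray(self.cell_length, dtype=float)
        if self.time_s.shape != self.cell_length.shape:
            raise TransientError("time and length arrays must have equal length")
        dt = np.diff(self.time_s)
        if np.any(dt <= 0):
            raise TransientError("time must be strictly increasing")
        if dt.size and (dt.max() - dt.min()) > 0.01 * dt.mean():
            raise TransientError("sampling must be uniform within 1%")
        duration = self.time_s[-1] - self.time_s[0]
        if duration * self.stimulus_rate_hz < 3:
            raise TransientError(
                f"trace must span >= 3 beats; got {duration:.2f} s at {self.stimulus_rate_hz} Hz"
            )

    @property
    def dt(self) -> float:
        return float(np.mean(np.diff(self.time_s)))


@dataclass
class BeatWindow:
    time_s: np.ndarray
    cell_length: np.ndarray
    onset_time_s: float


@dataclass
class BeatFeatures:
    l0: float                       # resting (pre-onset) length
    amplitude_pct: float            # 100 * (L0 - min length) / L0
    ttp90_s: Optional[float]        # onset -> 90% of peak shortening
    ttb90_s: Optional[float]        # peak -> 90% recovery of amplitude


@dataclass
class LusitropyResult:
    per_cell: dict                  # cell_id -> lusitropy value
    mean: float
    sem: Optional[float]
    p_value: Optional[float]        # paired t on ttb90 pre vs dob
    n_cells: int


@dataclass
class PairedResponse:
    deltas: dict                    # feature -> per-cell delta array
    means: dict                     # feature -> mean delta
    sems: dict
    p_values: dict
    stars: dict                     # feature -> "", "*" or "**"
    n_cells: int


def _smooth(y: np.ndarray, window: int = SMOOTH_WINDOW_SAMPLES) -> np.ndarray:
    if window <= 1 or y.size < window:
        return y.astype(float)
    kernel = np.ones(window) / window
    pad = window // 2
    ypad = np.pad(y.astype(float), pad, mode="edge")
    return np.convolve(ypad, kernel, mode="valid")[: y.size]


def _interp_crossing(t: np.ndarray, y: np.ndarray, level: float, rising: bool) -> Optional[float]:
    """First time y crosses ``level`` (in the given direction), interpolated."""
    for i in range(len(y) - 1):
        a, b = y[i], y[i + 1]
        hit = (a < level <= b) if rising else (a > level >= b)
        if hit:
            if b == a:
                return float(t[i])
            frac = (level - a) / (b - a)
            return float(t[i] + frac * (t[i + 1] - t[i]))
    return None


def segment_beats(trace: TransientTrace) -> list[BeatWindow]:
    """Split a trace into one window per detected contraction.

    Contraction onsets are threshold crossings of the smoothed negative
    length derivative, at most one per stimulus period; each window
    spans from 10% of a period before its onset to one period after.
    Warns when onset spacing is arrhythmic (CV of intervals > 20%),
    e.g. when a stimulus failed to elicit a beat.
    """
    y = _smooth(trace.cell_length)
    t = trace.time_s
    dt = trace.dt
    period = 1.0 / trace.stimulus_rate_hz
    deriv = np.gradient(y, t)
    amplitude = float(np.ptp(y))
    if amplitude <= 0 or np.ptp(deriv) == 0:
        raise TransientError(f"no detectable beats in trace {trace.cell_id!r} (flat)")
    thr = 0.3 * float(deriv.min())       # shortening = negative derivative
    if thr >= 0:
        raise TransientError(f"no detectable beats in trace {trace.cell_id!r}")

    refractory = int(round(0.5 * period / dt))
    onset_idx: list[int] = []
    i = 1
    while i < len(deriv):
        if deriv[i] < thr <= deriv[i - 1]:
            onset_idx.append(i)
            i += refractory
        else:
            i += 1
    if not onset_idx:
        raise TransientError(f"no detectable beats in trace {trace.cell_id!r}")

    if len(onset_idx) >= 3:
        gaps = np.diff(t[onset_idx])
        cv = gaps.std() / gaps.mean()
        if cv > 0.20:
            warnings.warn(
                f"arrhythmic beat spacing in trace {trace.cell_id!r} "
                f"(CV of onset intervals {cv:.2f} > 0.20)",
                stacklevel=2,
            )

    windows: list[BeatWindow] = []
    pre = int(round(0.1 * period / dt))
    post = int(round(period / dt))
    for idx in onset_idx:
        lo = max(0, idx - pre)
        hi = min(len(t), idx + post)
        seg_t, seg_y = t[lo:hi], trace.cell_length[lo:hi]
        # refine the onset to the 10%-amplitude crossing on the shortening phase
        ys = _smooth(seg_y)
        l0 = float(np.median(ys[: max(1, idx - lo)]))
        depth = l0 - float(ys.min())
        onset_time = _interp_crossing(seg_t, ys, l0 - ONSET_AMPLITUDE_FRACTION * depth, rising=False)
        if onset_time is None:
            onset_time = float(t[idx])
        windows.append(BeatWindow(seg_t, seg_y, onset_time))
    return windows


def beat_features(window: BeatWindow, smooth: bool = True) -> BeatFeatures:
    """Extract %L0, ttp90 and ttb90 from one beat window.

    L0 is the median length before the onset; ttp90 runs from the
    window's onset time to the first crossing of 90% of peak shortening
    (linear interpolation between samples); ttb90 runs from the peak to
    the recovery of 90% of the shortening amplitude toward L0.  A beat
    with no recovery inside the window reports ttb90 as None.
    """
    t = np.asarray(window.time_s, dtype=float)
    y = _smooth(np.asarray(window.cell_length, dtype=float)) if smooth else np.asarray(
        window.cell_length, dtype=float
    )
    pre_mask = t < window.onset_time_s
    l0 = float(np.median(y[pre_mask])) if pre_mask.any() else float(y[0])
    i_min = int(np.argmin(y))
    depth = l0 - float(y[i_min])
    if depth <= 0:
        raise TransientError("beat window has no shortening below the resting length")
    amplitude_pct = 100.0 * depth / l0

    # rise: from onset to peak; find 90%-of-peak-shortening crossing
    rise_mask = (t >= window.onset_time_s) & (t <= t[i_min])
    t90 = _interp_crossing(t[rise_mask], y[rise_mask], l0 - 0.9 * depth, rising=False)
    ttp90 = (t90 - window.onset_time_s) if t90 is not None else None

    # recovery: from peak onward, back up through 90% of the amplitude
    rec_t, rec_y = t[i_min:], y[i_min:]
    tb = _interp_crossing(rec_t, rec_y, l0 - 0.1 * depth, rising=True)
    ttb90 = (tb - float(t[i_min])) if tb is not None else None

    return BeatFeatures(l0=l0, amplitude_pct=amplitude_pct, ttp90_s=ttp90, ttb90_s=ttb90)


def trace_features(trace: TransientTrace) -> BeatFeatures:
    """Per-cell features: median over the accepted beats of one record."""
    feats = []
    for w in segment_beats(trace):
        try:
            feats.append(beat_features(w))
        except TransientError:
            continue
    if not feats:
        raise TransientError(f"no analysable beats in trace {trace.cell_id!r}")

    def med(values: list[Optional[float]]) -> Optional[float]:
        ok = [v for v in values if v is not None]
        return float(np.median(ok)) if ok else None

    return BeatFeatures(
        l0=float(np.median([f.l0 for f in feats])),
        amplitude_pct=float(np.median([f.amplitude_pct for f in feats])),
        ttp90_s=med([f.ttp90_s for f in feats]),
        ttb90_s=med([f.ttb90_s for f in feats]),
    )


def lusitropy(ttb90_pre_s: float, ttb90_dob_s: float) -> float:
    """Fractional change of ttb90 due to dobutamine: 1 - dob/pre.

    Positive values mean faster relaxation (lusitropy); negative values
    mean relaxation slowed, the uncoupled phenotype.
    """
    if ttb90_pre_s <= 0 or ttb90_dob_s <= 0:
        raise ValueError("ttb90 values must be positive")
    return 1.0 - ttb90_dob_s / ttb90_pre_s


def _star(p: Optional[float]) -> str:
    if p is None:
        return ""
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def paired_response(
    pre: dict[str, BeatFeatures],
    post: dict[str, BeatFeatures],
) -> PairedResponse:
    """Group statistics of the dobutamine response over paired cells.

    ``pre``/``post`` map cell ids to per-cell features before and after
    dobutamine.  Reports mean +/- SEM of per-cell deltas (post - pre)
    for amplitude_pct, ttp90 and ttb90 plus per-cell lusitropy, with
    two-tailed paired t-test p-values and the two-level star coding
    (* p < 0.05, ** p < 0.01).
    """
    unpaired = set(pre) ^ set(post)
    if unpaired:
        raise ValueError(f"unpaired cells: {sorted(unpaired)}")
    cells = sorted(pre)
    if len(cells) < 3:
        raise ValueError(f"need >= 3 paired cells, got {len(cells)}")

    def collect(attr: str) -> tuple[np.ndarray, np.ndarray]:
        a = np.array([getattr(pre[c], attr) for c in cells], dtype=float)
        b = np.array([getattr(post[c], attr) for c in cells], dtype=float)
        ok = np.isfinite(a) & np.isfinite(b)
        return a[ok], b[ok]

    deltas: dict[str, np.ndarray] = {}
    means: dict[str, float] = {}
    sems: dict[str, float] = {}
    p_values: dict[str, Optional[float]] = {}
    for attr in ("amplitude_pct", "ttp90_s", "ttb90_s"):
        a, b = collect(attr)
        d = b - a
        deltas[attr] = d
        means[attr] = float(d.mean())
        sems[attr] = float(d.std(ddof=1) / np.sqrt(d.size)) if d.size >= 2 else np.nan
        p_values[attr] = float(stats.ttest_rel(b, a).pvalue) if d.size >= 3 else None

    a, b = collect("ttb90_s")
    lus = 1.0 - b / a
    deltas["lusitropy"] = lus
    means["lusitropy"] = float(lus.mean())
    sems["lusitropy"] = float(lus.std(ddof=1) / np.sqrt(lus.size)) if lus.size >= 2 else np.nan
    p_values["lusitropy"] = float(stats.ttest_rel(b, a).pvalue) if lus.size >= 3 else None

    stars = {k: _star(v) for k, v in p_values.items()}
    return PairedResponse(
        deltas=deltas, means=means, sems=sems, p_values=p_values, stars=stars,
        n_cells=len(cells),
    )
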