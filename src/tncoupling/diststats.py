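"""Distribution summaries of metric series and the recoupling call.

Each metric series (helix A/B angle, hinge angle, interdomain
distance) is condensed to the statistics used to compare conditions:
sample mean and std, the full width at half maximum (FWHM) of a kernel
density estimate, and the percentage of samples strictly above a
boundary (110 deg for the A/B angle marks the open state of the
hydrophobic patch).  Differences between phosphorylated (P) and
unphosphorylated (uP) summaries give the phosphorylation delta; a
candidate condition "recouples" when its delta has the same sign as
the wild-type delta and exceeds a dead-band.

FWHM convention: Gaussian kernel density with Scott bandwidth on a
1024-point grid extended 3 bandwidths past the sample range; only the
global-maximum peak's half-height crossings are used (multimodal
densities therefore report the width of the main peak), crossings
located by linear interpolation.  For a Gaussian sample the FWHM
approaches 2*sqrt(2 ln 2)*sigma ~ 2.3548*sigma.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
from scipy.stats import gaussian_kde

__all__ = [
    "DistributionSummary",
    "PhosphoDelta",
    "RecouplingCall",
    "summarize",
    "delta",
    "classify_recoupling",
    "DEAD_BAND_ANGLE_DEG",
    "DEAD_BAND_DISTANCE_A",
    "DEAD_BAND_PCT",
]

GAUSSIAN_FWHM_FACTOR = 2.0 * np.sqrt(2.0 * np.log(2.0))

# default dead-bands for the recoupling call, by unit
DEAD_BAND_ANGLE_DEG = 0.5
DEAD_BAND_DISTANCE_A = 0.25
DEAD_BAND_PCT = 1.0


@dataclass
class DistributionSummary:
    mean: float
    std: float
    fwhm: float
    pct_above: Optional[float]      # percent of samples strictly above threshold
    threshold: Optional[float]
    n_samples: int
    units: str = "deg"
    metric_name: str = ""
    grid: Optional[np.ndarray] = None      # KDE grid (for plotting)
    density: Optional[np.ndarray] = None


@dataclass
class PhosphoDelta:
    """Phosphorylated-minus-unphosphorylated change of a summary."""

    uP: DistributionSummary
    P: DistributionSummary

    def __post_init__(self) -> None:
        if self.uP.metric_name != self.P.metric_name or self.uP.units != self.P.units:
            raise ValueError(
                f"cannot difference mismatched summaries: "
                f"{self.uP.metric_name}/{self.uP.units} vs {self.P.metric_name}/{self.P.units}"
            )

    @property
    def delta_mean(self) -> float:
        return self.P.mean - self.uP.mean

    @property
    def delta_fwhm(self) -> float:
        return self.P.fwhm - self.uP.fwhm

    @property
    def delta_pct_above(self) -> Optional[float]:
        if self.uP.pct_above is None or self.P.pct_above is None:
            return None
        return self.P.pct_above - self.uP.pct_above


@dataclass
class RecouplingCall:
    metric_name: str
    wt_delta: float
    test_delta: float
    dead_band: float
    restored: bool


def _fwhm_from_density(grid: np.ndarray, density: np.ndarray) -> float:
    ipk = int(np.argmax(density))
    half = density[ipk] / 2.0

    def cross(i_from: int, step: int) -> float:
        i = ipk
        while 0 <= i + step < len(grid):
            j = i + step
            if density[j] < half <= density[i]:
                # linear interpolation between grid[i] and grid[j]
                t = (density[i] - half) / (density[i] - density[j])
                return float(grid[i] + t * (grid[j] - grid[i]))
            i = j
        return float(grid[i])  # density never falls below half within the grid

    left = cross(ipk, -1)
    right = cross(ipk, +1)
    return right - left


def summarize(
    values: Union[np.ndarray, "list[float]"],
    threshold: Optional[float] = None,
    units: str = "deg",
    metric_name: str = "",
    grid_points: int = 1024,
    keep_density: bool = False,
) -> DistributionSummary:
    """Summarize pooled samples of one metric.

    ``pct_above`` is computed on the samples (strict >), not on KDE
    area, and is reported in percent.  Raises on fewer than 10 samples
    or a degenerate (all-identical) sample.
    """
    x = np.asarray(values, dtype=float).ravel()
    if x.size < 10:
        raise ValueError(f"need >= 10 samples to summarize, got {x.size}")
    if not np.all(np.isfinite(x)):
        raise ValueError("samples contain non-finite values")
    if np.ptp(x) == 0.0:
        raise ValueError("all samples identical: density is degenerate")

    kde = gaussian_kde(x)  # Scott bandwidth
    h = float(kde.factor * x.std(ddof=1))
    grid = np.linspace(x.min() - 3 * h, x.max() + 3 * h, grid_points)
    density = kde(grid)
    fwhm = _fwhm_from_density(grid, density)

    pct = None
    if threshold is not None:
        pct = 100.0 * float(np.count_nonzero(x > threshold)) / x.size

    return DistributionSummary(
        mean=float(x.mean()),
        std=float(x.std(ddof=1)),
        fwhm=float(fwhm),
        pct_above=pct,
        threshold=threshold,
        n_samples=int(x.size),
        units=units,
        metric_name=metric_name,
        grid=grid if keep_density else None,
        density=density if keep_density else None,
    )


def delta(uP: DistributionSummary, P: DistributionSummary) -> PhosphoDelta:
    """Phosphorylation delta, sign convention P minus uP."""
    return PhosphoDelta(uP=uP, P=P)


def classify_recoupling(
    wt_delta: Union[PhosphoDelta, float],
    candidate_delta: Union[PhosphoDelta, float],
    dead_band: float = DEAD_BAND_ANGLE_DEG,
    metric_name: str = "",
) -> RecouplingCall:
    """Does the candidate reproduce the wild-type phosphorylation shift?

    Restored iff the candidate delta has the same sign as the wild-type
    delta and its magnitude exceeds the dead-band (so near-zero shifts
    never count as restored).  Deltas may be given as PhosphoDelta
    objects (their delta_mean is used) or plain numbers.
    """
    if dead_band < 0:
        raise ValueError(f"dead_band must be >= 0, got {dead_band}")
    if isinstance(wt_delta, PhosphoDelta):
        if not metric_name:
            metric_name = wt_delta.uP.metric_name
        wt_delta = wt_delta.delta_mean
    if isinstance(candidate_delta, PhosphoDelta):
        candidate_delta = candidate_delta.delta_mean
    restored = (
        np.sign(candidate_delta) == np.sign(wt_delta)
        and abs(candidate_delta) > dead_band
    )
    return RecouplingCall(
        metric_name=metric_name,
        wt_delta=float(wt_delta),
        test_delta=float(candidate_delta),
        dead_band=float(dead_band),
        restored=bool(restored),
    )
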