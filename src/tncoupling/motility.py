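"""Ca2+-activation curves from in vitro motility assays and the coupling call.

In the in vitro motility assay, the fraction of thin filaments moving
over immobilised myosin is measured across a range of free [Ca2+].
The activation curve is fitted with a four-parameter Hill model

    f([Ca]) = f_min + (f_max - f_min) / (1 + (EC50 / [Ca])**n_H)

and the coupling between troponin-I phosphorylation and Ca2+
sensitivity is read from the EC50 ratio of the phosphorylated (P) to
the unphosphorylated (unP) state: a 2-3 fold desensitisation on
phosphorylation means coupled; a ratio near 1 means the mutation has
uncoupled Ca2+ sensitivity from the phosphorylation level.  A
fixed-[Ca2+] paired screen (fraction motile P vs unP at one
concentration) gives a rapid coupled/uncoupled readout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence
import warnings

import numpy as np
from scipy import optimize, stats

__all__ = [
    "ActivationCurve",
    "HillFit",
    "CouplingResult",
    "ScreenResult",
    "FitError",
    "hill",
    "fit_hill",
    "coupling_ratio",
    "coupling_call",
    "fixed_ca_screen",
    "DEFAULT_COUPLING_RATIO_THRESHOLD",
]

#: mean P/unP EC50 ratio above which a condition is called coupled
DEFAULT_COUPLING_RATIO_THRESHOLD = 1.5


class FitError(RuntimeError):
    """Hill fit failed to converge or produced an invalid optimum."""


@dataclass
class ActivationCurve:
    """Fraction motile vs [Ca2+] for one replicate and phospho state."""

    ca_um: np.ndarray             # micromolar, > 0
    fraction_motile: np.ndarray   # in [0, 1] up to noise
    phospho_state: str = "unP"    # "P" or "unP"
    replicate_id: str = "r1"
    condition: str = ""           # troponin variant + ligand label
    units: str = "uM"

    def __post_init__(self) -> None:
        self.ca_um = np.asarray(self.ca_um, dtype=float)
        self.fraction_motile = np.asarray(self.fraction_motile, dtype=float)
        if self.ca_um.shape != self.fraction_motile.shape:
            raise ValueError("ca_um and fraction_motile must have equal length")
        if np.any(self.ca_um <= 0):
            raise ValueError("[Ca2+] values must be positive")
        if np.unique(self.ca_um).size < 5:
            raise ValueError(
                f"need >= 5 distinct [Ca2+] for fitting, got {np.unique(self.ca_um).size}"
            )


@dataclass
class HillFit:
    ec50: float                   # same units as the curve (uM)
    n_h: float
    f_max: float
    f_min: float
    residual_ss: float
    stderr: dict = field(default_factory=dict)
    units: str = "uM"

    def __post_init__(self) -> None:
        if not np.isfinite(self.ec50) or self.ec50 <= 0:
            raise FitError(f"fitted EC50 must be positive and finite, got {self.ec50}")
        if self.f_min > self.f_max:
            raise FitError("fitted f_min exceeds f_max")


@dataclass
class CouplingResult:
    ratios: list[float]           # per replicate pair, EC50(P)/EC50(unP)
    mean_ratio: float
    sem_ratio: Optional[float]    # None for n = 1
    p_value: Optional[float]      # paired t on log EC50; None when n < 3
    coupled: bool
    threshold: float
    significance_available: bool


@dataclass
class ScreenResult:
    mean_p: float
    mean_unp: float
    p_value: float
    positive: bool                # coupled: motility suppressed by phosphorylation
    n_pairs: int


def hill(ca: np.ndarray, ec50: float, n_h: float, f_min: float, f_max: float) -> np.ndarray:
    """Four-parameter Hill activation curve."""
    ca = np.asarray(ca, dtype=float)
    return f_min + (f_max - f_min) / (1.0 + (ec50 / ca) ** n_h)


def _hill_log(log_ca: np.ndarray, log_ec50: float, n_h: float, f_min: float, f_max: float) -> np.ndarray:
    # fitting in log-concentration keeps the problem well-scaled
    return f_min + (f_max - f_min) / (1.0 + 10.0 ** (n_h * (log_ec50 - log_ca)))


def fit_hill(curve: ActivationCurve) -> HillFit:
    """Least-squares Hill fit with free EC50, n_H, f_min, f_max.

    Fitting is done on log10[Ca2+].  A flat curve (no activation range)
    raises :class:`FitError`.  Warns, without failing, when the fitted
    EC50 lies outside the measured concentration span.
    """
    ca = curve.ca_um
    f = curve.fraction_motile
    if np.ptp(f) < 0.05:
        raise FitError(
            f"activation range {np.ptp(f):.3f} too small to fit "
            f"(condition {curve.condition!r}, replicate {curve.replicate_id})"
        )
    log_ca = np.log10(ca)
    # initial guesses: EC50 at half-activation crossing, n_H = 2
    f0, f1 = float(f.min()), float(f.max())
    half = (f0 + f1) / 2.0
    i_half = int(np.argmin(np.abs(f - half)))
    p0 = [float(log_ca[i_half]), 2.0, f0, f1]
    lo = [log_ca.min() - 3.0, 0.1, -0.5, 0.0]
    hi = [log_ca.max() + 3.0, 10.0, 1.0, 1.5]
    try:
        popt, pcov = optimize.curve_fit(
            _hill_log, log_ca, f, p0=p0, bounds=(lo, hi), maxfev=20000
        )
    except (RuntimeError, optimize.OptimizeWarning) as exc:
        raise FitError(
            f"Hill fit did not converge for condition {curve.condition!r} "
            f"replicate {curve.replicate_id}: {exc}"
        ) from exc
    log_ec50, n_h, f_min, f_max = popt
    ec50 = float(10.0 ** log_ec50)
    resid = f - _hill_log(log_ca, *popt)
    if not (ca.min() <= ec50 <= ca.max()):
        warnings.warn(
            f"fitted EC50 {ec50:.3g} {curve.units} lies outside the measured "
            f"[Ca2+] span [{ca.min():.3g}, {ca.max():.3g}]",
            stacklevel=2,
        )
    perr = np.sqrt(np.diag(pcov)) if np.all(np.isfinite(pcov)) else np.full(4, np.nan)
    stderr = {
        "ec50": float(ec50 * np.log(10.0) * perr[0]),  # delta method from log10 EC50
        "n_h": float(perr[1]),
        "f_min": float(perr[2]),
        "f_max": float(perr[3]),
    }
    return HillFit(
        ec50=ec50,
        n_h=float(n_h),
        f_max=float(f_max),
        f_min=float(f_min),
        residual_ss=float(np.sum(resid**2)),
        stderr=stderr,
        units=curve.units,
    )


def coupling_ratio(fit_p: HillFit, fit_unp: HillFit) -> float:
    """EC50(P) / EC50(unP); > 1 means phosphorylation desensitises."""
    if fit_p.units != fit_unp.units:
        raise ValueError(f"unit mismatch: {fit_p.units} vs {fit_unp.units}")
    return fit_p.ec50 / fit_unp.ec50


def coupling_call(
    pairs: Sequence[tuple[HillFit, HillFit]],
    threshold: float = DEFAULT_COUPLING_RATIO_THRESHOLD,
    alpha: float = 0.05,
) -> CouplingResult:
    """Coupling call over replicate (P, unP) fit pairs.

    The reported ratio is the mean of per-pair ratios (with SEM for
    n >= 2); significance is a two-tailed paired t-test on log EC50,
    available only for n >= 3.  Coupled requires mean ratio above the
    threshold and, when testable, p < alpha.
    """
    if len(pairs) == 0:
        raise ValueError("need at least one (P, unP) fit pair")
    ratios = [coupling_ratio(p, u) for p, u in pairs]
    mean_ratio = float(np.mean(ratios))
    n = len(ratios)
    sem = float(np.std(ratios, ddof=1) / np.sqrt(n)) if n >= 2 else None
    p_value = None
    if n >= 3:
        log_p = np.log([p.ec50 for p, _ in pairs])
        log_u = np.log([u.ec50 for _, u in pairs])
        p_value = float(stats.ttest_rel(log_p, log_u).pvalue)
    coupled = mean_ratio > threshold and (p_value is None or p_value < alpha)
    return CouplingResult(
        ratios=ratios,
        mean_ratio=mean_ratio,
        sem_ratio=sem,
        p_value=p_value,
        coupled=bool(coupled),
        threshold=threshold,
        significance_available=p_value is not None,
    )


def fixed_ca_screen(
    fraction_motile_p: Sequence[float],
    fraction_motile_unp: Sequence[float],
    alpha: float = 0.05,
) -> ScreenResult:
    """Rapid coupling screen at a single [Ca2+].

    Paired measurements of fraction motile with and without
    phosphorylation; positive (coupled) iff phosphorylation
    significantly lowers motility (mean P < mean unP, paired two-tailed
    t-test p < alpha).
    """
    p = np.asarray(fraction_motile_p, dtype=float)
    u = np.asarray(fraction_motile_unp, dtype=float)
    if p.shape != u.shape:
        raise ValueError("P and unP measurements must be paired (equal length)")
    if p.size < 3:
        raise ValueError(f"need >= 3 paired measurements, got {p.size}")
    if np.allclose(p, u):
        p_value = 1.0
    else:
        p_value = float(stats.ttest_rel(p, u).pvalue)
    positive = (p.mean() < u.mean()) and (p_value < alpha)
    return ScreenResult(
        mean_p=float(p.mean()),
        mean_unp=float(u.mean()),
        p_value=p_value,
        positive=bool(positive),
        n_pairs=int(p.size),
    )
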