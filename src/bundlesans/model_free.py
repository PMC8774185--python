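"""Model-free analyses of 1D SAS curves.

Implements the standard dilute-solution toolbox: Guinier regression for
(Rg, I(0)), a Debye random-coil fit, the Kratky transform with a coarse
fold-state classification, forward-intensity molecular-weight ratios
against a standard sample, and a two-Guinier decomposition that bounds the
number fraction of large aggregates from low-Q excess intensity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Tuple

import numpy as np
from scipy import optimize, signal

from .sas_io import ScatteringCurve

__all__ = [
    "GuinierResult", "DebyeResult", "KratkyProfile", "MwRatioResult",
    "AggregateEstimate", "guinier_fit", "debye_fit", "debye_function",
    "kratky_transform", "mw_ratio", "aggregate_fraction",
]

# Guinier window of the reference SANS study, in Q^2 (1/A^2)
DEFAULT_Q2_WINDOW = (0.001, 0.002)
QRG_GUIDELINE = 1.3


@dataclass
class GuinierResult:
    """Guinier fit: ln I = ln I(0) - (Rg^2/3) Q^2 over a low-Q window."""
    rg: float
    rg_err: float
    i0: float
    i0_err: float
    q2_range: Tuple[float, float]
    qrg_max: float
    r_squared: float
    n_points: int
    qrg_warning: bool = False


@dataclass
class DebyeResult:
    """Gaussian-coil (Debye function) fit of a scattering curve."""
    rg: float
    rg_err: float
    i0: float
    i0_err: float
    chi2_reduced: float
    q_range: Tuple[float, float]


@dataclass
class KratkyProfile:
    """Kratky transform Q^2 I(Q) with shape features and a classification.

    classification is one of "folded" (low-Q bell, no high-Q plateau),
    "random_coil" (plateau without a bell) or "partially_flexible" (both,
    or neither feature resolvable).
    """
    q: np.ndarray
    y: np.ndarray
    classification: str
    bell_peak_q: Optional[float]
    plateau_level: Optional[float]
    features: dict = field(default_factory=dict)


@dataclass
class MwRatioResult:
    """Molecular-weight ratio from forward intensities per concentration:
    MW/MW_st = [I(0)/C] / [I(0)_st/C_st] (times a known MW_st ratio)."""
    i0: float
    c: float
    i0_st: float
    c_st: float
    ratio: float
    ratio_rounded: float


@dataclass
class AggregateEstimate:
    """Two-population low-Q decomposition (monomer + large aggregate)."""
    fraction: float            # number fraction of aggregated particles
    monomer_i0: float
    aggregate_i0: float
    size_ratio: float          # Rg_aggregate / Rg_monomer, assumed
    note: str = ""


def _window_mask(curve: ScatteringCurve, q2_min: float, q2_max: float) -> np.ndarray:
    q2 = curve.q ** 2
    return (q2 >= q2_min) & (q2 <= q2_max)


def guinier_fit(
    curve: ScatteringCurve,
    q2_min: float = DEFAULT_Q2_WINDOW[0],
    q2_max: float = DEFAULT_Q2_WINDOW[1],
    enforce_qrg: bool = True,
) -> GuinierResult:
    """Weighted linear regression of ln I(Q) on Q^2 over [q2_min, q2_max].

    Returns Rg = sqrt(-3 * slope) and I(0) = exp(intercept) with errors
    propagated from the regression covariance.  Points with non-positive
    intensity inside the window are masked (log-space operation).  If
    ``enforce_qrg`` and Q*Rg at the window edge exceeds 1.3, a warning
    flag is set on the result — not an error, since unfolded states are
    conventionally fit beyond the guideline.
    """
    m = _window_mask(curve, q2_min, q2_max) & (curve.intensity > 0)
    n = int(m.sum())
    if n < 3:
        raise ValueError(
            f"need >= 3 points with positive intensity in Q^2 window "
            f"[{q2_min:g}, {q2_max:g}]; found {n}"
        )
    x = curve.q[m] ** 2
    y = np.log(curve.intensity[m])
    if curve.sigma is not None:
        # sigma(ln I) = sigma_I / I
        w = (curve.intensity[m] / np.where(curve.sigma[m] > 0,
                                           curve.sigma[m], np.inf)) ** 2
        if not np.any(w > 0):
            w = np.ones_like(x)
        w[w == 0] = np.min(w[w > 0]) if np.any(w > 0) else 1.0
    else:
        w = np.ones_like(x)
    A = np.column_stack([np.ones_like(x), x])
    AtW = A.T * w
    cov = np.linalg.inv(AtW @ A)
    beta = cov @ (AtW @ y)
    intercept, slope = beta
    if slope >= 0:
        raise ValueError("no Guinier decay in window (non-negative slope)")
    resid = y - A @ beta
    dof = max(n - 2, 1)
    s2 = float(resid @ (w * resid)) / dof
    cov = cov * s2
    rg = float(np.sqrt(-3.0 * slope))
    rg_err = float(np.sqrt(cov[1, 1]) * 3.0 / (2.0 * rg)) if rg > 0 else np.inf
    i0 = float(np.exp(intercept))
    i0_err = float(i0 * np.sqrt(cov[0, 0]))
    ybar = np.average(y, weights=w)
    ss_tot = float(np.sum(w * (y - ybar) ** 2))
    r2 = 1.0 - float(resid @ (w * resid)) / ss_tot if ss_tot > 0 else 1.0
    qrg_max = float(np.sqrt(x.max()) * rg)
    flagged = bool(enforce_qrg and qrg_max > QRG_GUIDELINE)
    if flagged:
        warnings.warn(
            f"Q*Rg = {qrg_max:.2f} at the window edge exceeds the Guinier "
            f"guideline {QRG_GUIDELINE}", stacklevel=2)
    return GuinierResult(rg=rg, rg_err=rg_err, i0=i0, i0_err=i0_err,
                         q2_range=(float(x.min()), float(x.max())),
                         qrg_max=qrg_max, r_squared=r2, n_points=n,
                         qrg_warning=flagged)


def debye_function(q: np.ndarray, rg: float) -> np.ndarray:
    """Debye function D(Q) = 2 (e^{-u} + u - 1)/u^2 with u = (Q Rg)^2.

    The scattering form factor of an ideal Gaussian (random-walk) chain.
    Small-u values are evaluated by series expansion for stability.
    """
    u = (np.asarray(q, dtype=float) * rg) ** 2
    out = np.empty_like(u)
    small = u < 1e-4
    us = u[small]
    out[small] = 1.0 - us / 3.0 + us ** 2 / 12.0 - us ** 3 / 60.0
    ub = u[~small]
    out[~small] = 2.0 * (np.expm1(-ub) + ub) / ub ** 2
    return out


def debye_fit(
    curve: ScatteringCurve,
    q_range: Optional[Tuple[float, float]] = None,
    init_rg: Optional[float] = None,
) -> DebyeResult:
    """Weighted nonlinear least-squares fit of I(Q) = I(0) D(Q; Rg).

    ``init_rg=None`` seeds Rg from a Guinier pass over the default window
    (falling back to 20 A); on non-convergence a restart grid over
    {5, 10, 20, 40, 80} A is tried before giving up.
    """
    sub = curve if q_range is None else curve.crop(*q_range)
    if len(sub) < 10:
        raise ValueError(f"need >= 10 points in fit range; found {len(sub)}")
    if init_rg is None:
        try:
            init_rg = guinier_fit(sub, enforce_qrg=False).rg
        except ValueError:
            init_rg = 20.0
    sigma = sub.sigma if sub.sigma is not None else np.ones_like(sub.q)
    sigma = np.where(sigma > 0, sigma, np.nanmedian(sigma[sigma > 0])
                     if np.any(sigma > 0) else 1.0)

    def model(q, i0, rg):
        return i0 * debye_function(q, rg)

    i0_guess = float(np.clip(sub.intensity[0], 1e-12, None))
    best = None
    for rg0 in [init_rg, 5.0, 10.0, 20.0, 40.0, 80.0]:
        try:
            popt, pcov = optimize.curve_fit(
                model, sub.q, sub.intensity, p0=[i0_guess, rg0],
                sigma=sigma, absolute_sigma=sub.sigma is not None,
                bounds=([0, 0.1], [np.inf, 1e4]), maxfev=20000)
        except (RuntimeError, ValueError):
            continue
        resid = (sub.intensity - model(sub.q, *popt)) / sigma
        chi2 = float(resid @ resid)
        if best is None or chi2 < best[2]:
            best = (popt, pcov, chi2)
    if best is None:
        raise RuntimeError("Debye fit failed to converge from the restart grid")
    popt, pcov, chi2 = best
    dof = max(len(sub) - 2, 1)
    perr = np.sqrt(np.diag(pcov))
    return DebyeResult(rg=float(popt[1]), rg_err=float(perr[1]),
                       i0=float(popt[0]), i0_err=float(perr[0]),
                       chi2_reduced=chi2 / dof,
                       q_range=(float(sub.q[0]), float(sub.q[-1])))


# Kratky shape-feature defaults (config-exposed; qualitative shape criteria
# made quantitative here)
KRATKY_BELL_QMAX = 0.15        # 1/A: bell peak must lie below this
KRATKY_PLATEAU_QMIN = 0.20     # 1/A: plateau assessed above this
KRATKY_BELL_PROMINENCE = 0.25  # bell peak must exceed high-Q median by 25%
KRATKY_PLATEAU_FLATNESS = 0.20  # relative change over the plateau window
KRATKY_PLATEAU_SIGNIFICANCE = 0.3  # plateau level relative to the profile peak


def _smooth(y: np.ndarray) -> np.ndarray:
    n = len(y)
    win = min(11, n if n % 2 == 1 else n - 1)
    if win < 5:
        return y.copy()
    return signal.savgol_filter(y, window_length=win, polyorder=2)


def kratky_transform(
    curve: ScatteringCurve,
    bell_qmax: float = KRATKY_BELL_QMAX,
    plateau_qmin: float = KRATKY_PLATEAU_QMIN,
    bell_prominence: float = KRATKY_BELL_PROMINENCE,
    plateau_flatness: float = KRATKY_PLATEAU_FLATNESS,
) -> KratkyProfile:
    """Kratky transform y = Q^2 I(Q) with fold-state classification.

    A "bell" is a local maximum of the smoothed transform below
    ``bell_qmax`` exceeding the high-Q median by ``bell_prominence``; a
    "plateau" is a smoothed high-Q region (Q > ``plateau_qmin``) whose
    relative drift stays within ``plateau_flatness`` of flat.  A weaker,
    broader bell — an interior global maximum (at most 90% of the way to
    the last Q point) followed by a decline of more than 10% — is also
    recorded: rod-like partially folded structures peak above the strict
    low-Q bell boundary while a Gaussian coil rises monotonically onto its
    plateau.  Compactly folded particles show the strict bell without the
    plateau, random coils the plateau with no bell of either kind, and
    partially flexible structures anything in between.
    """
    y = curve.q ** 2 * curve.intensity
    ys = _smooth(y)
    hi = curve.q > plateau_qmin
    lo = curve.q < bell_qmax
    hi_median = float(np.median(ys[hi])) if np.any(hi) else np.nan

    bell_peak_q = None
    if np.count_nonzero(lo) >= 3:
        yl = ys[lo]
        ql = curve.q[lo]
        peaks, _ = signal.find_peaks(yl)
        ref = hi_median if np.isfinite(hi_median) else float(np.median(ys))
        cand = [p for p in peaks if yl[p] >= (1.0 + bell_prominence) * ref]
        if cand:
            best = max(cand, key=lambda p: yl[p])
            bell_peak_q = float(ql[best])

    # broad-bell feature: interior global maximum followed by a clear
    # decline (a coil's Kratky transform rises monotonically to its
    # plateau and never turns over)
    broad_bell_q = None
    ipk = int(np.argmax(ys))
    if (curve.q[ipk] <= 0.9 * curve.q[-1] and ys[ipk] > 0
            and ys[-1] < 0.9 * ys[ipk]):
        broad_bell_q = float(curve.q[ipk])

    plateau_level = None
    has_plateau = False
    if np.count_nonzero(hi) >= 5:
        qh, yh = curve.q[hi], ys[hi]
        level = float(np.mean(yh))
        if level > 0:
            slope = np.polyfit(qh, yh, 1)[0]
            rel_change = slope * (qh[-1] - qh[0]) / level
            # a coil-like plateau is both flat and a significant fraction
            # of the profile maximum; the residual incoherent floor under
            # a folded particle's bell is flat but an order of magnitude
            # below the bell and does not indicate chain flexibility
            if (abs(rel_change) <= plateau_flatness
                    and level >= KRATKY_PLATEAU_SIGNIFICANCE * float(ys.max())):
                has_plateau = True
                plateau_level = level

    if bell_peak_q is not None and not has_plateau:
        cls = "folded"
    elif has_plateau and bell_peak_q is None and broad_bell_q is None:
        cls = "random_coil"
    else:
        cls = "partially_flexible"
    return KratkyProfile(
        q=curve.q, y=y, classification=cls,
        bell_peak_q=bell_peak_q, plateau_level=plateau_level,
        features={"high_q_median": hi_median,
                  "has_plateau": has_plateau,
                  "broad_bell_q": broad_bell_q},
    )


def round_half_up(x: float, decimals: int = 1) -> float:
    """Decimal half-up rounding (3 digit printing convention, not banker's)."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def mw_ratio(i0: float, c: float, i0_st: float, c_st: float,
             mw_st_ratio: float = 1.0) -> MwRatioResult:
    """Molecular-weight ratio from forward intensity per concentration.

    MW/MW_st = [I(0)/C] / [I(0)_st/C_st] * mw_st_ratio.  The rounded value
    uses half-up rounding to one decimal, the convention of printed MW
    ratio tables.
    """
    for name, v in (("i0", i0), ("c", c), ("i0_st", i0_st), ("c_st", c_st),
                    ("mw_st_ratio", mw_st_ratio)):
        if not v > 0:
            raise ValueError(f"{name} must be > 0, got {v}")
    ratio = (i0 / c) / (i0_st / c_st) * mw_st_ratio
    return MwRatioResult(i0=i0, c=c, i0_st=i0_st, c_st=c_st, ratio=ratio,
                         ratio_rounded=round_half_up(ratio, 1))


def aggregate_fraction(
    curve: ScatteringCurve,
    monomer_fit: GuinierResult,
    aggregate_rg: float = 100.0,
    q_max: Optional[float] = None,
) -> AggregateEstimate:
    """Bound the number fraction of large aggregates from low-Q excess.

    Fits a two-population Guinier sum
    I(Q) = i0_m exp(-Q^2 rg_m^2/3) + i0_a exp(-Q^2 rg_a^2/3)
    over the low-Q region with (rg_m, i0_m) held near ``monomer_fit`` and
    rg_a fixed at ``aggregate_rg``.  Per particle I(0) scales with the
    squared particle volume, so with v = (rg_a/rg_m)^3 the number ratio is
    n_a/n_m = (i0_a/i0_m)/v^2 and the reported fraction is
    n_a/(n_a + n_m).  All assumptions (the assumed aggregate size and the
    volume-squared weighting) are echoed in the result.
    """
    if q_max is None:
        q_max = 3.0 / aggregate_rg  # Q*Rg_a <= 3 keeps the big-particle term sane
    sub = curve.crop(0.0, q_max)
    if len(sub) < 4:
        sub = ScatteringCurve(q=curve.q[:6], intensity=curve.intensity[:6],
                              sigma=None if curve.sigma is None
                              else curve.sigma[:6])
    rg_m, i0_m0 = monomer_fit.rg, monomer_fit.i0
    mono = i0_m0 * np.exp(-sub.q ** 2 * rg_m ** 2 / 3.0)
    excess = sub.intensity - mono
    if not np.any(excess > 0):
        return AggregateEstimate(fraction=0.0, monomer_i0=i0_m0,
                                 aggregate_i0=0.0,
                                 size_ratio=aggregate_rg / rg_m,
                                 note="no low-Q excess above the monomer "
                                      "Guinier extrapolation")
    sigma = sub.sigma if sub.sigma is not None else np.ones_like(sub.q)
    sigma = np.where(sigma > 0, sigma, 1.0)

    def model(q, i0m, i0a):
        return (i0m * np.exp(-q ** 2 * rg_m ** 2 / 3.0)
                + i0a * np.exp(-q ** 2 * aggregate_rg ** 2 / 3.0))

    popt, _ = optimize.curve_fit(
        model, sub.q, sub.intensity, p0=[i0_m0, max(float(excess.max()), 1e-12)],
        sigma=sigma,
        bounds=([0.5 * i0_m0, 0.0], [1.5 * i0_m0, np.inf]), maxfev=20000)
    i0_m, i0_a = map(float, popt)
    size_ratio = aggregate_rg / rg_m
    vol_ratio = size_ratio ** 3
    n_ratio = (i0_a / i0_m) / vol_ratio ** 2  # per-particle I(0) ~ V^2
    frac = n_ratio / (1.0 + n_ratio)
    return AggregateEstimate(fraction=float(frac), monomer_i0=i0_m,
                             aggregate_i0=i0_a, size_ratio=size_ratio,
                             note=f"assumed aggregate Rg = {aggregate_rg:g} A; "
                                  "per-particle I(0) taken proportional to V^2")
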