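"""Surface tension, area strain, and area-compressibility-modulus estimation.

The lateral tension of a bilayer follows from the pressure-tensor
anisotropy scaled by the box height,

    gamma = L_z * (P_zz - (P_xx + P_yy) / 2),

converted bar·Å → mN/m.  The area compressibility modulus K_A is the slope
of tension versus area strain eps_A = (A - A0)/A0 across a series of runs
at imposed tensions, with the gamma = 0 run defining the reference area A0.
Uncertainties on trajectory averages use the integrated-autocorrelation
(statistical inefficiency) correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .units import BAR_ANGSTROM_TO_MN_PER_M

__all__ = [
    "PressureRecord",
    "TensionPoint",
    "ElasticityResult",
    "TTestResult",
    "surface_tension",
    "area_strain",
    "stationary_se",
    "fit_area_compressibility",
    "compare_ka",
    "critical_t",
]


@dataclass
class PressureRecord:
    """Diagonal pressure-tensor components (bar) and box height (Å)."""

    p_xx: float
    p_yy: float
    p_zz: float
    l_z: float
    time: float = 0.0

    def __post_init__(self) -> None:
        if self.l_z <= 0:
            raise ValueError(f"L_z must be positive, got {self.l_z}")


@dataclass
class TensionPoint:
    """One tension condition: imposed gamma with its mean APL and SE."""

    gamma: float        # mN/m
    apl_mean: float     # Å²
    apl_se: float       # Å²
    n_eff: float = 1.0

    def __post_init__(self) -> None:
        if self.apl_se < 0:
            raise ValueError("apl_se must be >= 0")
        if self.n_eff < 1:
            raise ValueError("n_eff must be >= 1")


@dataclass
class ElasticityResult:
    ka: float                   # mN/m
    ka_se: float                # mN/m
    a0: float                   # Å², APL at gamma = 0
    a0_se: float                # Å²
    strains: np.ndarray         # eps_A per fitted point
    gammas: np.ndarray          # mN/m per fitted point
    residuals: np.ndarray       # gamma - ka * eps_A
    r_squared: float
    weighted: bool = True
    through_origin: bool = True


@dataclass
class TTestResult:
    t: float
    df: int
    p: float
    significant: bool
    alpha: float = 0.05


def surface_tension(records) -> tuple[np.ndarray, float]:
    """Per-record and mean surface tension (mN/m) from pressure records.

    Accepts a sequence of :class:`PressureRecord` or an (n, 4) array of
    columns ``(P_xx, P_yy, P_zz, L_z)``.
    """
    if hasattr(records, "__len__") and len(records) == 0:
        raise ValueError("surface_tension requires at least one record")
    if isinstance(records, np.ndarray):
        arr = np.asarray(records, dtype=float)
        pxx, pyy, pzz, lz = arr[:, 0], arr[:, 1], arr[:, 2], arr[:, 3]
    else:
        pxx = np.array([r.p_xx for r in records])
        pyy = np.array([r.p_yy for r in records])
        pzz = np.array([r.p_zz for r in records])
        lz = np.array([r.l_z for r in records])
    gamma = lz * (pzz - 0.5 * (pxx + pyy)) * BAR_ANGSTROM_TO_MN_PER_M
    return gamma, float(np.mean(gamma))


def area_strain(a, a0: float):
    """Area strain eps_A = (A - A0) / A0."""
    if a0 <= 0:
        raise ValueError(f"reference area A0 must be positive, got {a0}")
    return (np.asarray(a, dtype=float) - a0) / a0


def stationary_se(series) -> tuple[float, float]:
    """Standard error of the mean of a correlated (stationary) series.

    The integrated autocorrelation time ``tau`` is the sum of the normalized
    autocorrelation function from lag 1 up to (excluding) the first negative
    value; the effective sample size is ``n_eff = N / (1 + 2 tau)`` and
    ``se = sd / sqrt(n_eff)``.

    Returns ``(se, n_eff)``.  A constant series yields ``(0.0, N)``.
    """
    x = np.asarray(series, dtype=float).ravel()
    n = x.size
    if n < 10:
        raise ValueError(f"stationary_se needs at least 10 samples, got {n}")
    if np.ptp(x) == 0.0:
        return 0.0, float(n)
    x = x - x.mean()
    c0 = float(np.dot(x, x)) / n
    if c0 == 0.0:
        return 0.0, float(n)
    # biased autocovariance via FFT
    nfft = 1 << (2 * n - 1).bit_length()
    f = np.fft.rfft(x, nfft)
    acov = np.fft.irfft(f * np.conj(f), nfft)[:n] / n
    rho = acov / c0
    neg = np.nonzero(rho[1:] < 0)[0]
    kmax = neg[0] + 1 if neg.size else n
    tau = float(np.sum(rho[1:kmax]))
    tau = max(tau, 0.0)
    n_eff = n / (1.0 + 2.0 * tau)
    n_eff = float(min(max(n_eff, 1.0), n))
    sd = float(np.sqrt(c0 * n / (n - 1)))
    return sd / np.sqrt(n_eff), n_eff


def fit_area_compressibility(
    points,
    weighted: bool = True,
    through_origin: bool = True,
) -> ElasticityResult:
    """Fit K_A from a series of tension conditions.

    Exactly one point must have gamma = 0; its mean APL defines A0 and its SE
    propagates into the K_A uncertainty.  The default estimator regresses the
    (noisy) strains on the (imposed, exact) tensions with weights 1/se², a
    slope ``b`` whose reciprocal is K_A; the A0 contribution is added in
    quadrature.  ``weighted=False`` falls back to ordinary least squares of
    gamma on strain; ``through_origin=False`` frees the intercept (diagnostic
    only — the reference point pins the line at the origin by construction).
    """
    points = list(points)
    if len(points) < 2:
        raise ValueError("need at least 2 tension points")
    gammas_all = np.array([p.gamma for p in points], dtype=float)
    ref = [i for i, g in enumerate(gammas_all) if np.isclose(g, 0.0)]
    if len(ref) != 1:
        raise ValueError(
            f"exactly one gamma = 0 point is required to define A0, found {len(ref)}"
        )
    iref = ref[0]
    a0 = points[iref].apl_mean
    a0_se = points[iref].apl_se
    if a0 <= 0:
        raise ValueError("A0 must be positive")

    others = [p for i, p in enumerate(points) if i != iref]
    gam = np.array([p.gamma for p in others], dtype=float)
    if np.unique(np.round(gammas_all, 12)).size < 2:
        raise ValueError("need at least 2 distinct gamma values")
    eps = area_strain(np.array([p.apl_mean for p in others]), a0)
    if len(eps) > 1 and np.allclose(eps, eps[0]):
        raise ValueError("all strains identical; K_A is undefined")
    se_eps = np.array([p.apl_se for p in others], dtype=float) / a0

    if weighted and np.all(se_eps > 0):
        w = 1.0 / se_eps**2
        swg2 = float(np.sum(w * gam**2))
        b = float(np.sum(w * gam * eps)) / swg2          # slope of eps on gamma
        if b == 0:
            raise ValueError("zero tension response; K_A is undefined")
        var_b = 1.0 / swg2
        ka = 1.0 / b
        se_slope = np.sqrt(var_b) / b**2                  # d(1/b) = -db/b²
        # A0 error shifts all strains by ~ -dA0/A0 in common
        shift_sens = abs(float(np.sum(w * gam))) / swg2
        se_a0_part = (a0_se / a0) * shift_sens / b**2
        ka_se = float(np.hypot(se_slope, se_a0_part))
    else:
        # OLS of gamma on eps (exact-data / unweighted route)
        if through_origin:
            denom = float(np.sum(eps**2))
            if denom == 0:
                raise ValueError("all strains are zero; K_A is undefined")
            ka = float(np.sum(eps * gam)) / denom
            dof = max(len(gam) - 1, 1)
            resid = gam - ka * eps
            var_ka = float(np.sum(resid**2)) / dof / denom
        else:
            slope, intercept = np.polyfit(eps, gam, 1)
            ka = float(slope)
            resid = gam - (slope * eps + intercept)
            dof = max(len(gam) - 2, 1)
            sxx = float(np.sum((eps - eps.mean()) ** 2))
            var_ka = float(np.sum(resid**2)) / dof / sxx if sxx > 0 else 0.0
        se_slope = np.sqrt(var_ka)
        ka_se = float(np.hypot(se_slope, abs(ka) * a0_se / a0))

    resid = gam - ka * eps
    ss_tot = float(np.sum((gam - gam.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    return ElasticityResult(
        ka=float(ka), ka_se=float(ka_se), a0=float(a0), a0_se=float(a0_se),
        strains=np.concatenate([[0.0], eps]),
        gammas=np.concatenate([[0.0], gam]),
        residuals=resid, r_squared=r2,
        weighted=weighted, through_origin=through_origin,
    )


def critical_t(df: int, alpha: float = 0.05) -> float:
    """Two-tailed critical value of Student's t."""
    return float(stats.t.ppf(1.0 - alpha / 2.0, df))


def compare_ka(
    ka1: float, se1: float, ka2: float, se2: float,
    n1: int = 4, n2: int = 4, alpha: float = 0.05,
) -> TTestResult:
    """Pooled-variance two-sample t test between two K_A estimates.

    Group standard deviations are reconstructed from the standard errors as
    ``sd = se * sqrt(n)``, with each group contributing one estimate per
    tension condition (default n = 4, df = 6).
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("group sizes must be >= 2")
    if (se1 < 0) or (se2 < 0):
        raise ValueError("standard errors must be >= 0")
    df = n1 + n2 - 2
    sd1, sd2 = se1 * np.sqrt(n1), se2 * np.sqrt(n2)
    sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / df
    denom = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    diff = ka1 - ka2
    if denom == 0:
        t = 0.0 if diff == 0 else np.inf * np.sign(diff)
    else:
        t = diff / denom
    p = float(2.0 * stats.t.sf(abs(t), df)) if np.isfinite(t) else 0.0
    tcrit = critical_t(df, alpha)
    return TTestResult(t=float(t), df=int(df), p=p,
                       significant=bool(abs(t) > tcrit), alpha=alpha)


def compare_ka_z(ka1: float, se1: float, ka2: float, se2: float,
                 alpha: float = 0.05) -> TTestResult:
    """Alternative z comparison using the fitted-slope SEs directly."""
    denom = float(np.hypot(se1, se2))
    z = 0.0 if denom == 0 and ka1 == ka2 else (ka1 - ka2) / denom
    p = float(2.0 * stats.norm.sf(abs(z)))
    return TTestResult(t=float(z), df=0, p=p,
                       significant=bool(p < alpha), alpha=alpha)
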