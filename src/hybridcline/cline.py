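"""Maximum-likelihood cumulative-normal (probit) cline fitting.

The cline model is F(X) = Phi(m*X + b), where Phi is the standard normal
CDF, X is the along-transect distance in km, and (m, b) are the slope and
intercept estimated by maximizing the Bernoulli log-likelihood

    l(m, b) = sum_i [ y_i * ln Phi(m x_i + b) + (1 - y_i) * ln(1 - Phi(m x_i + b)) ].

Derived statistics follow from the definition of a normal distribution:
the center (50% point) is -b/m, the maximum slope is |m|/sqrt(2*pi), and
the 20-80% width is 1.68/|m| (1.68 approximates 2 * z_0.8 = 1.6832; the
rounded constant is used deliberately, see docs).

The optimizer is Newton-Raphson with step-halving, falling back to a
golden-section search on the profile likelihood in m if the observed
information matrix is singular.  Complete separation (the likelihood
supremum at infinite slope) is detected and flagged rather than returned
as a silent pseudo-fit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

SQRT_2PI = math.sqrt(2.0 * math.pi)
WIDTH_CONSTANT = 1.68  # 20-80% width = 1.68/|m|; rounded from 2*z_{0.8}

_TOL_LL = 1e-10
_TOL_GRAD = 1e-8
_MAX_ITER = 200
_ETA_SEPARATION = 30.0  # |m x + b| beyond this on all points => separation


class DegenerateResponseError(ValueError):
    """Raised when the response contains only one class."""


@dataclass(frozen=True)
class ClineObservation:
    """One projected specimen: along-transect distance and binary class.

    ``y`` = 1 conventionally codes the "common"/eastern clade, 0 the
    Florida-peninsula clade; the coding only flips the signs of (m, b).
    """

    x: float
    y: int

    def __post_init__(self) -> None:
        if not math.isfinite(self.x) or self.x < 0:
            raise ValueError("x must be finite and >= 0")
        if self.y not in (0, 1):
            raise ValueError("y must be 0 or 1")


@dataclass(frozen=True)
class ClineFit:
    """ML probit parameters with convergence diagnostics.

    ``standard_errors`` are from the inverse observed information; they
    are (nan, nan) when the fit did not converge.
    """

    m: float
    b: float
    log_likelihood: float
    n_obs: int
    converged: bool
    standard_errors: tuple[float, float]
    diagnostics: str = ""
    n_iter: int = 0


@dataclass(frozen=True)
class ClineStats:
    center_km: float
    max_slope_per_km: float
    width_20_80_km: float


def _loglik(m: float, b: float, x: np.ndarray, y: np.ndarray) -> float:
    eta = m * x + b
    # logcdf/logsf are stable far into the tails
    return float(np.sum(np.where(y == 1, norm.logcdf(eta), norm.logsf(eta))))


def _score_info(m: float, b: float, x: np.ndarray, y: np.ndarray):
    """Gradient and observed information of the probit log-likelihood."""
    eta = m * x + b
    phi = norm.pdf(eta)
    # lambda_i = d l_i / d eta_i ; stable via exp(logpdf - logcdf)
    lam1 = np.exp(norm.logpdf(eta) - norm.logcdf(eta))      # y=1 branch
    lam0 = -np.exp(norm.logpdf(eta) - norm.logsf(eta))      # y=0 branch
    lam = np.where(y == 1, lam1, lam0)
    # -d2 l_i / d eta_i^2 = lam_i * (lam_i + eta_i)  (positive for probit)
    w = lam * (lam + eta)
    g = np.array([np.sum(lam * x), np.sum(lam)])
    info = np.array([
        [np.sum(w * x * x), np.sum(w * x)],
        [np.sum(w * x), np.sum(w)],
    ])
    return g, info, phi


def fit_probit_cline(obs: list[ClineObservation]) -> ClineFit:
    """Fit Phi(m*x + b) to binary observations by maximum likelihood.

    Requires at least two observations in each class and non-constant x.
    Returns ``converged=False`` with a diagnostic message when the data
    are completely separated (the ML slope is infinite) or Newton fails.

    Raises
    ------
    DegenerateResponseError
        If all responses belong to one class.
    ValueError
        If fewer than two observations per class or x is constant.
    """
    x = np.asarray([o.x for o in obs], dtype=float)
    y = np.asarray([o.y for o in obs], dtype=float)
    n = len(obs)
    n1 = int(y.sum())
    if n1 == 0 or n1 == n:
        raise DegenerateResponseError("degenerate response: only one class present")
    if n1 < 2 or n - n1 < 2:
        raise ValueError("need at least 2 observations in each class")
    if np.ptp(x) == 0:
        raise ValueError("x values are all identical")

    m, b = 0.0, float(norm.ppf(y.mean()))
    ll = _loglik(m, b, x, y)
    n_iter = 0
    for n_iter in range(1, _MAX_ITER + 1):
        g, info, _ = _score_info(m, b, x, y)
        try:
            step = np.linalg.solve(info, g)
        except np.linalg.LinAlgError:
            return _golden_section_fallback(x, y, m, b)
        if not np.all(np.isfinite(step)):
            return _golden_section_fallback(x, y, m, b)
        # step-halving line search
        scale = 1.0
        for _ in range(40):
            m_new, b_new = m + scale * step[0], b + scale * step[1]
            ll_new = _loglik(m_new, b_new, x, y)
            if ll_new >= ll - 1e-13:
                break
            scale *= 0.5
        else:
            return ClineFit(m, b, ll, n, False, (math.nan, math.nan),
                            "line search failed", n_iter)
        delta = ll_new - ll
        m, b, ll = m_new, b_new, ll_new
        gnorm = float(np.linalg.norm(_score_info(m, b, x, y)[0]))
        eta = m * x + b
        if np.min(np.abs(eta)) > _ETA_SEPARATION or abs(m) > 1e6:
            return ClineFit(m, b, ll, n, False, (math.nan, math.nan),
                            "complete separation suspected: |m*x+b| diverging", n_iter)
        if abs(delta) < _TOL_LL and gnorm < _TOL_GRAD:
            # a "converged" state with every point fit essentially perfectly
            # is separation with an underflowed gradient, not a true optimum
            if np.min(np.abs(eta)) > 6.0 or ll > -1e-6:
                return ClineFit(m, b, ll, n, False, (math.nan, math.nan),
                                "complete separation suspected: all points fit perfectly",
                                n_iter)
            _, info, _ = _score_info(m, b, x, y)
            try:
                cov = np.linalg.inv(info)
                se = (math.sqrt(cov[0, 0]), math.sqrt(cov[1, 1]))
            except (np.linalg.LinAlgError, ValueError):
                se = (math.nan, math.nan)
            return ClineFit(m, b, ll, n, True, se, "", n_iter)
    return ClineFit(m, b, ll, n, False, (math.nan, math.nan),
                    "maximum iterations reached", n_iter)


def _profile_b(m: float, x: np.ndarray, y: np.ndarray, b0: float) -> tuple[float, float]:
    """Maximize over b at fixed m by 1-D Newton; returns (b_hat, ll)."""
    b = b0
    for _ in range(100):
        g, info, _ = _score_info(m, b, x, y)
        if info[1, 1] <= 0:
            break
        step = g[1] / info[1, 1]
        b_new = b + step
        if abs(step) < 1e-12:
            b = b_new
            break
        b = b_new
    return b, _loglik(m, b, x, y)


def _golden_section_fallback(x: np.ndarray, y: np.ndarray, m0: float, b0: float) -> ClineFit:
    """Golden-section search on the profile likelihood in m.

    Used when the Newton information matrix is singular; brackets m in a
    wide window around a coarse grid maximum.
    """
    span = 10.0 / max(np.ptp(x), 1.0)
    grid = np.linspace(-span, span, 201)
    lls = []
    b = b0
    for mm in grid:
        b, ll = _profile_b(mm, x, y, b)
        lls.append(ll)
    k = int(np.argmax(lls))
    lo = grid[max(0, k - 1)]
    hi = grid[min(len(grid) - 1, k + 1)]
    invphi = (math.sqrt(5.0) - 1.0) / 2.0
    a_, b_ = lo, hi
    c = b_ - invphi * (b_ - a_)
    d = a_ + invphi * (b_ - a_)
    fc = _profile_b(c, x, y, b0)[1]
    fd = _profile_b(d, x, y, b0)[1]
    for _ in range(200):
        if b_ - a_ < 1e-12:
            break
        if fc > fd:
            b_, d, fd = d, c, fc
            c = b_ - invphi * (b_ - a_)
            fc = _profile_b(c, x, y, b0)[1]
        else:
            a_, c, fc = c, d, fd
            d = a_ + invphi * (b_ - a_)
            fd = _profile_b(d, x, y, b0)[1]
    m = 0.5 * (a_ + b_)
    b_hat, ll = _profile_b(m, x, y, b0)
    eta = m * x + b_hat
    if np.min(np.abs(eta)) > 6.0 or ll > -1e-6:
        return ClineFit(m, b_hat, ll, len(x), False, (math.nan, math.nan),
                        "complete separation suspected (profile fallback)", 0)
    _, info, _ = _score_info(m, b_hat, x, y)
    try:
        cov = np.linalg.inv(info)
        se = (math.sqrt(cov[0, 0]), math.sqrt(cov[1, 1]))
        converged = True
    except (np.linalg.LinAlgError, ValueError):
        se = (math.nan, math.nan)
        converged = False
    return ClineFit(m, b_hat, ll, len(x), converged, se, "profile fallback used", 0)


def derive_cline_stats(fit: ClineFit | tuple[float, float]) -> ClineStats:
    """Center, maximum slope, and 20-80% width from probit parameters.

    center = -b/m (the X where m*X + b = 0, i.e. F = 0.5);
    max_slope = |m|/sqrt(2*pi); width = 1.68/|m|.

    Accepts a ClineFit or a bare (m, b) pair.  Raises for m = 0 (flat
    cline, width undefined).
    """
    if isinstance(fit, ClineFit):
        m, b = fit.m, fit.b
    else:
        m, b = fit
    if m == 0:
        raise ValueError("flat cline, width undefined")
    return ClineStats(
        center_km=-b / m,
        max_slope_per_km=abs(m) / SQRT_2PI,
        width_20_80_km=WIDTH_CONSTANT / abs(m),
    )


def predict_frequency(fit: ClineFit | tuple[float, float], x) -> float | np.ndarray:
    """Fitted frequency F(X) = Phi(m*X + b) of the y=1 class at X."""
    if isinstance(fit, ClineFit):
        m, b = fit.m, fit.b
    else:
        m, b = fit
    out = norm.cdf(m * np.asarray(x, dtype=float) + b)
    return float(out) if np.ndim(x) == 0 else out


@dataclass(frozen=True)
class BootstrapResult:
    center_ci: tuple[float, float]
    width_ci: tuple[float, float]
    n_boot: int
    n_converged: int
    centers: np.ndarray = field(repr=False)
    widths: np.ndarray = field(repr=False)


def bootstrap_cline_ci(obs: list[ClineObservation], n_boot: int, seed: int) -> BootstrapResult:
    """Case-resampling bootstrap percentile intervals for center and width.

    Non-convergent or degenerate replicates are dropped and counted; an
    error is raised if more than half of the replicates fail, or if the
    fit to the original data does not converge.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    base = fit_probit_cline(obs)
    if not base.converged:
        raise ValueError(f"fit on original data did not converge: {base.diagnostics}")
    rng = np.random.default_rng(seed)
    n = len(obs)
    centers, widths = [], []
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        sample = [obs[i] for i in idx]
        try:
            fit = fit_probit_cline(sample)
        except (DegenerateResponseError, ValueError):
            continue
        if not fit.converged or fit.m == 0:
            continue
        st = derive_cline_stats(fit)
        centers.append(st.center_km)
        widths.append(st.width_20_80_km)
    if len(centers) < n_boot / 2:
        raise ValueError(
            f"bootstrap unstable: only {len(centers)}/{n_boot} replicates converged")
    centers_a = np.asarray(centers)
    widths_a = np.asarray(widths)
    c_ci = tuple(np.percentile(centers_a, [2.5, 97.5]))
    w_ci = tuple(np.percentile(widths_a, [2.5, 97.5]))
    return BootstrapResult(c_ci, w_ci, n_boot, len(centers), centers_a, widths_a)
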