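"""Conditional extremal dependence model on Laplace margins.

For a bivariate vector (Y_c, Y_r) with standard Laplace margins, the
conditional-extremes model describes the response given a large conditioning
value y > u as

    Y_r | Y_c = y  =  a * y + y^b * Z,        a in [-1, 1],  b < 1,

where Z is a non-degenerate residual variable independent of Y_c in the limit.
The sign of `a` encodes positive vs negative extremal dependence; a = 1, b = 0
is perfect (asymptotic) dependence, a = 0, b = 0 independence, and 0 < a < 1
with b > 0 the sub-asymptotic association typical of, e.g., Gaussian
dependence (where a = rho^2, b = 1/2).

Estimation uses the standard working pseudo-likelihood in which Z is treated
as i.i.d. Gaussian with free location mu and scale sigma — so Y_r | Y_c = y is
modelled with mean a*y + mu*y^b and standard deviation sigma*y^b. For fixed
(a, b) the nuisance (mu, sigma) profiles out in closed form, leaving a
two-dimensional search. The residual distribution used downstream is the
empirical distribution of the standardized residuals, not the working model.

Additional joint constraints on (a, b) keep the fitted conditional quantiles
inside the envelope implied by perfect positive (respectively negative)
dependence at and beyond the observed data range, which prevents inferences
inconsistent with the margins.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .marginal import laplace_quantile

_DEFAULT_STARTS = (
    (0.01, 0.2),
    (0.5, 0.5),
    (-0.5, 0.5),
    (0.9, 0.1),
    (-0.9, 0.1),
)
_SIGMA2_FLOOR = 1e-20


@dataclass
class DependenceFit:
    """Fitted conditional-extremes dependence model for one (response | conditioning) pair."""

    a: float
    b: float
    mu: float
    sigma: float
    q_dep: float
    dep_threshold: float  # Laplace-scale conditioning threshold
    residuals: np.ndarray = field(repr=False)
    cond_exceedances: np.ndarray = field(repr=False)
    resp_exceedances: np.ndarray = field(repr=False)
    negloglik: float = np.nan
    n_starts: int = 0
    b_unidentified: bool = False

    @property
    def n_exceedances(self) -> int:
        return len(self.residuals)

    def conditional_quantile(self, y: np.ndarray, prob: float) -> np.ndarray:
        """Fitted conditional quantile of the response at conditioning value(s) y."""
        zq = float(np.quantile(self.residuals, prob))
        y = np.asarray(y, dtype=float)
        return self.a * y + np.power(y, self.b) * zq

    def to_dict(self) -> dict:
        return {
            "a": self.a, "b": self.b, "mu": self.mu, "sigma": self.sigma,
            "q_dep": self.q_dep, "dep_threshold": self.dep_threshold,
            "n_exceedances": self.n_exceedances, "negloglik": self.negloglik,
            "b_unidentified": self.b_unidentified,
        }


def constraints_feasible(
    a: float,
    b: float,
    z_lo: float,
    z_hi: float,
    v_max: float,
) -> bool:
    """Joint feasibility of (a, b) given extreme residual quantiles.

    True iff, for every conditioning value v at and beyond ``v_max`` (the
    largest observed conditioning exceedance, positive on the Laplace scale),
    the fitted conditional quantiles stay inside the perfect-dependence
    envelope:

        a*v + v^b * z_hi <= v     (never above perfect positive dependence)
        a*v + v^b * z_lo >= -v    (never below perfect negative dependence)

    Because b < 1, each bound holds for all v >= v_max iff it holds at v_max
    (with the degenerate |a| = 1 cases requiring the residual quantile on the
    relevant side to be non-positive / non-negative).
    """
    if not (-1.0 <= a <= 1.0) or not (b < 1.0) or v_max <= 0:
        return False
    # upper envelope, comparison with perfect positive dependence
    if z_hi > 0:
        if a >= 1.0:
            return False
        if (1.0 - a) * v_max ** (1.0 - b) < z_hi:
            return False
    # lower envelope, comparison with perfect negative dependence
    if z_lo < 0:
        if a <= -1.0:
            return False
        if (1.0 + a) * v_max ** (1.0 - b) < -z_lo:
            return False
    return True


def _profile_nll(a: float, b: float, y: np.ndarray, yr: np.ndarray) -> tuple[float, float, float]:
    """Working-model NLL at (a, b) with (mu, sigma) profiled out in closed form."""
    z = (yr - a * y) / np.power(y, b)
    mu = float(np.mean(z))
    s2 = max(float(np.mean((z - mu) ** 2)), _SIGMA2_FLOOR)
    n = len(y)
    nll = 0.5 * n * np.log(2.0 * np.pi * s2) + b * float(np.sum(np.log(y))) + 0.5 * n
    return nll, mu, float(np.sqrt(s2))


def _quantile_sorted(zs: np.ndarray, q: float) -> float:
    """Linear-interpolation quantile of an already-sorted array."""
    h = (len(zs) - 1) * q
    i = int(h)
    if i + 1 >= len(zs):
        return float(zs[-1])
    return float(zs[i] + (h - i) * (zs[i + 1] - zs[i]))


def _penalized_objective(theta, y, yr, logy, sum_logy, constrain, q_lo, q_hi, v_max):
    # reject pathological corners of the unconstrained coordinates (b below -20
    # underflows y^b to zero for large y)
    if not np.all(np.isfinite(theta)) or theta[1] > 3.0:
        return 1e12
    a = np.tanh(theta[0])
    b = 1.0 - np.exp(theta[1])
    z = (yr - a * y) * np.exp(-b * logy)
    mu = z.mean()
    s2 = max(float(((z - mu) ** 2).mean()), _SIGMA2_FLOOR)
    n = len(y)
    nll = 0.5 * n * np.log(2.0 * np.pi * s2) + b * sum_logy + 0.5 * n
    if constrain:
        zs = np.sort(z)
        z_lo = _quantile_sorted(zs, q_lo)
        z_hi = _quantile_sorted(zs, q_hi)
        if not constraints_feasible(a, b, z_lo, z_hi, v_max):
            return nll + 1e10
    return nll


def fit_conditional(
    y_resp: np.ndarray,
    y_cond: np.ndarray,
    q_dep: float = 0.9,
    min_exceedances: int = 10,
    constrain: bool = True,
    constraint_quantiles: tuple[float, float] = (0.025, 0.975),
    starts=_DEFAULT_STARTS,
) -> DependenceFit:
    """Fit the conditional dependence model above the ``q_dep`` conditioning quantile.

    Both inputs must already be on the standard Laplace scale. The dependence
    threshold is the theoretical Laplace quantile of ``q_dep`` (the margins are
    standard Laplace by construction). Multi-start Nelder-Mead over
    unconstrained coordinates (atanh a, log(1-b)); candidates violating the
    joint envelope constraints are rejected by penalty.
    """
    y_resp = np.asarray(y_resp, dtype=float)
    y_cond = np.asarray(y_cond, dtype=float)
    if y_resp.shape != y_cond.shape:
        raise ValueError("response and conditioning arrays must be aligned")
    if not 0.5 <= q_dep < 1.0:
        raise ValueError("q_dep must lie in [0.5, 1) so the threshold is non-negative")
    u = float(laplace_quantile(q_dep)[0])
    mask = y_cond > u
    if int(mask.sum()) < min_exceedances:
        raise ValueError(
            f"only {int(mask.sum())} conditioning exceedances above q_dep={q_dep}; "
            f"need at least {min_exceedances}"
        )
    y, yr = y_cond[mask], y_resp[mask]
    q_lo, q_hi = constraint_quantiles
    v_max = float(np.max(y))

    logy = np.log(y)
    args = (y, yr, logy, float(np.sum(logy)), constrain, q_lo, q_hi, v_max)
    thetas = [
        (float(np.arctanh(np.clip(a0, -0.999, 0.999))), float(np.log(1.0 - min(b0, 0.999))))
        for a0, b0 in starts
    ]
    best = None
    for theta0 in thetas:
        res = optimize.minimize(
            _penalized_objective, theta0, args=args,
            method="Nelder-Mead",
            options={"xatol": 1e-6, "fatol": 1e-9, "maxiter": 600},
        )
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun) or best.fun >= 1e9:
        raise RuntimeError(
            f"no feasible optimum found over {len(starts)} starts "
            f"(best objective {None if best is None else best.fun})"
        )
    a = float(np.tanh(best.x[0]))
    b = float(1.0 - np.exp(best.x[1]))
    nll, mu, sigma = _profile_nll(a, b, y, yr)
    z = (yr - a * y) / np.power(y, b)
    return DependenceFit(
        a=a, b=b, mu=mu, sigma=sigma, q_dep=q_dep, dep_threshold=u,
        residuals=z, cond_exceedances=y, resp_exceedances=yr,
        negloglik=nll, n_starts=len(starts),
        b_unidentified=bool(np.std(z) < 1e-6),
    )


def profile_surface(
    y_resp: np.ndarray,
    y_cond: np.ndarray,
    q_dep: float = 0.9,
    a_grid: np.ndarray | None = None,
    b_grid: np.ndarray | None = None,
    constrain: bool = True,
    constraint_quantiles: tuple[float, float] = (0.025, 0.975),
) -> pd.DataFrame:
    """Profile negative log-likelihood over an (a, b) grid with feasibility mask.

    (mu, sigma) are optimized out in closed form at every node. Returns a long
    table with columns a, b, nll, feasible.
    """
    if a_grid is None:
        a_grid = np.linspace(-0.99, 0.99, 41)
    if b_grid is None:
        b_grid = np.linspace(-1.5, 0.95, 41)
    y_resp = np.asarray(y_resp, dtype=float)
    y_cond = np.asarray(y_cond, dtype=float)
    u = float(laplace_quantile(q_dep)[0])
    mask = y_cond > u
    y, yr = y_cond[mask], y_resp[mask]
    v_max = float(np.max(y))
    q_lo, q_hi = constraint_quantiles
    rows = []
    for a in a_grid:
        for b in b_grid:
            nll, _, _ = _profile_nll(float(a), float(b), y, yr)
            feas = True
            if constrain:
                z = (yr - a * y) / np.power(y, b)
                z_lo, z_hi = np.quantile(z, [q_lo, q_hi])
                feas = constraints_feasible(float(a), float(b), float(z_lo), float(z_hi), v_max)
            rows.append({"a": float(a), "b": float(b), "nll": nll, "feasible": feas})
    surf = pd.DataFrame(rows)
    if not surf["feasible"].any():
        raise RuntimeError("empty feasible region on the requested grid")
    return surf


def threshold_stability(
    y_resp: np.ndarray,
    y_cond: np.ndarray,
    quantile_grid: np.ndarray | None = None,
    n_boot: int = 25,
    min_exceedances: int = 10,
    seed: int | None = None,
) -> pd.DataFrame:
    """Refit (a, b) across candidate dependence thresholds with bootstrap bands.

    A stable trace over the candidate quantiles supports the chosen threshold.
    Candidates leaving too few exceedances are flagged rather than fitted.
    """
    if quantile_grid is None:
        quantile_grid = np.arange(0.50, 0.901, 0.05)
    y_resp = np.asarray(y_resp, dtype=float)
    y_cond = np.asarray(y_cond, dtype=float)
    rng = np.random.default_rng(seed)
    n = len(y_resp)
    rows = []
    for q in np.round(np.asarray(quantile_grid, dtype=float), 10):
        u = float(laplace_quantile(q)[0])
        n_exc = int(np.sum(y_cond > u))
        if n_exc < min_exceedances:
            rows.append({"q_dep": q, "a": np.nan, "b": np.nan,
                         "a_lo": np.nan, "a_hi": np.nan,
                         "b_lo": np.nan, "b_hi": np.nan,
                         "n_exceedances": n_exc, "fitted": False})
            continue
        try:
            fit = fit_conditional(y_resp, y_cond, q_dep=q, min_exceedances=min_exceedances)
        except (ValueError, RuntimeError):
            rows.append({"q_dep": q, "a": np.nan, "b": np.nan,
                         "a_lo": np.nan, "a_hi": np.nan,
                         "b_lo": np.nan, "b_hi": np.nan,
                         "n_exceedances": n_exc, "fitted": False})
            continue
        a_bs, b_bs = [], []
        for _ in range(n_boot):
            idx = rng.integers(0, n, size=n)
            try:
                f = fit_conditional(y_resp[idx], y_cond[idx], q_dep=q,
                                    min_exceedances=min_exceedances,
                                    starts=((fit.a, min(fit.b, 0.9)),))
                a_bs.append(f.a)
                b_bs.append(f.b)
            except (ValueError, RuntimeError):
                continue
        def band(v):
            return (np.nan, np.nan) if len(v) < 2 else tuple(np.quantile(v, [0.025, 0.975]))
        a_lo, a_hi = band(a_bs)
        b_lo, b_hi = band(b_bs)
        rows.append({"q_dep": q, "a": fit.a, "b": fit.b,
                     "a_lo": a_lo, "a_hi": a_hi, "b_lo": b_lo, "b_hi": b_hi,
                     "n_exceedances": n_exc, "fitted": True})
    return pd.DataFrame(rows)


def residual_independence_diag(fit: DependenceFit, n_bins: int = 4) -> dict:
    """Rank-correlation check that residuals are independent of the conditioning variable.

    The model assumes Z independent of Y_c above the threshold; a strong rank
    correlation between the standardized residuals and the conditioning
    exceedances indicates the threshold is too low or the model inadequate.
    Binned residual location/scale summaries accompany the test.
    """
    if fit.n_exceedances < 10:
        raise ValueError("need at least 10 residuals for the independence diagnostic")
    if np.std(fit.residuals) < 1e-12:
        return {"applicable": False, "reason": "degenerate residuals (zero spread)"}
    rho, pval = stats.spearmanr(fit.cond_exceedances, fit.residuals)
    edges = np.quantile(fit.cond_exceedances, np.linspace(0, 1, n_bins + 1))
    edges[-1] += 1e-9
    bins = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        m = (fit.cond_exceedances >= lo) & (fit.cond_exceedances < hi)
        if m.sum() >= 2:
            bins.append({"y_lo": float(lo), "y_hi": float(hi),
                         "n": int(m.sum()),
                         "z_mean": float(np.mean(fit.residuals[m])),
                         "z_sd": float(np.std(fit.residuals[m], ddof=1))})
    return {"applicable": True, "spearman_rho": float(rho),
            "p_value": float(pval), "bins": bins}
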