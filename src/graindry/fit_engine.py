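"""Nonlinear least-squares fitting with drying-literature fit statistics.

Any registered closed-form model (drying or shrinkage) is fitted by
bounded trust-region least squares with seeded multi-start.  The
goodness-of-fit surface follows the conventions of the thin-layer drying
literature:

* R^2 reported as a percentage,
* mean relative error  P = (100/n) * sum(|Y - Yhat| / Y)  (percent),
* average estimated error  SE = sqrt(SSE / GLR)  with GLR = n - p
  residual degrees of freedom (response units),
* a runs test on residual signs classifying the residual distribution as
  random or tendentious,
* a lexicographic model ranking: random residuals first, then P below an
  acceptability threshold, then smallest SE, then largest R^2.

The runs test is one-sided: a model is flagged *tendentious* when the
observed number of sign runs is significantly too small (systematic
drift); an excess of runs carries no evidence of trend.  The run-count
p-value is computed from the exact conditional distribution of runs.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import least_squares
from scipy.special import gammaln

from ._errors import ContractError
from .models import ModelSpec

__all__ = [
    "FitResult",
    "fit_model",
    "r_squared",
    "mean_relative_error_P",
    "standard_error_SE",
    "classify_residuals",
    "runs_test_pvalue",
    "rank_models",
    "brute_force_fit",
]

RANDOM = "random"
TENDENTIOUS = "tendentious"


@dataclass
class FitResult:
    """Outcome of one model fit with the full statistics block."""

    model_name: str
    params: dict[str, float]
    r2_pct: float
    se: float
    p_pct: float
    residual_class: str
    n_obs: int
    glr: int
    converged: bool
    sse: float
    at_bounds: tuple[str, ...] = field(default=())
    param_se: dict[str, float] = field(default_factory=dict)
    param_t: dict[str, float] = field(default_factory=dict)

    def to_row(self) -> dict:
        row = {
            "model": self.model_name,
            "r2_pct": self.r2_pct,
            "se": self.se,
            "p_pct": self.p_pct,
            "residual_class": self.residual_class,
            "n_obs": self.n_obs,
            "glr": self.glr,
            "converged": self.converged,
            "sse": self.sse,
        }
        for k, v in self.params.items():
            row[f"param_{k}"] = v
        return row


# ---------------------------------------------------------------------------
# statistics


def r_squared(y: Sequence[float], yhat: Sequence[float]) -> float:
    """Coefficient of determination as a percentage, 100*(1 - SSE/SStot)."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.size < 2 or y.shape != yhat.shape:
        raise ContractError("need >= 2 paired observations")
    sstot = float(np.sum((y - y.mean()) ** 2))
    if sstot == 0:
        raise ContractError("R^2 undefined for constant observations")
    sse = float(np.sum((y - yhat) ** 2))
    return 100.0 * (1.0 - sse / sstot)


def mean_relative_error_P(y: Sequence[float], yhat: Sequence[float]) -> float:
    """Mean relative error P = (100/n) * sum(|Y - Yhat| / Y), percent."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape or y.size == 0:
        raise ContractError("need equal-length non-empty observations")
    if np.any(y == 0):
        raise ContractError("P undefined when an observed value is zero")
    return float(100.0 / y.size * np.sum(np.abs(y - yhat) / np.abs(y)))


def standard_error_SE(y: Sequence[float], yhat: Sequence[float], glr: int) -> float:
    """Average estimated error SE = sqrt(sum((Y - Yhat)^2) / GLR)."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape:
        raise ContractError("mismatched lengths")
    if glr < 1:
        raise ContractError("GLR (residual degrees of freedom) must be >= 1")
    return float(np.sqrt(np.sum((y - yhat) ** 2) / glr))


def _log_comb(n: int, k: int) -> float:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def runs_test_pvalue(n_pos: int, n_neg: int, runs: int) -> float:
    """Exact lower-tail p-value P(R <= runs) of the two-sample runs count.

    Conditional on ``n_pos`` positive and ``n_neg`` negative signs, the
    number of runs R has the classical combinatorial distribution; too
    few runs indicate sign clustering (trend).
    """
    n = n_pos + n_neg
    if n_pos == 0 or n_neg == 0:
        return 1.0 if runs >= 1 else 0.0
    log_total = _log_comb(n, n_pos)
    p = 0.0
    for r in range(2, runs + 1):
        if r % 2 == 0:
            k = r // 2
            lp = (
                np.log(2.0)
                + _log_comb(n_pos - 1, k - 1)
                + _log_comb(n_neg - 1, k - 1)
                - log_total
            )
            p += np.exp(lp)
        else:
            k = (r - 1) // 2
            terms = 0.0
            if k >= 1:
                if n_neg - 1 >= k:
                    terms += np.exp(
                        _log_comb(n_pos - 1, k - 1) + _log_comb(n_neg - 1, k)
                    )
                if n_pos - 1 >= k:
                    terms += np.exp(
                        _log_comb(n_pos - 1, k) + _log_comb(n_neg - 1, k - 1)
                    )
            p += terms * np.exp(-log_total)
    return float(min(p, 1.0))


def classify_residuals(
    residuals: Sequence[float], alpha: float = 0.05
) -> str:
    """Classify a residual sequence as ``random`` or ``tendentious``.

    Runs test on residual signs; zero residuals inherit the preceding
    sign (leading zeros count as positive).  An all-zero residual vector
    (perfect fit) is random by convention; a single-signed vector is
    tendentious.
    """
    r = np.asarray(residuals, dtype=float)
    if r.size < 5:
        raise ContractError("need >= 5 residuals for the runs test")
    if np.all(r == 0):
        return RANDOM
    signs = np.where(r > 0, 1, np.where(r < 0, -1, 0))
    prev = 1
    for i, s in enumerate(signs):
        if s == 0:
            signs[i] = prev
        else:
            prev = s
    n_pos = int(np.sum(signs > 0))
    n_neg = int(np.sum(signs < 0))
    runs = int(1 + np.sum(signs[1:] != signs[:-1]))
    if n_pos == 0 or n_neg == 0:
        return TENDENTIOUS
    p = runs_test_pvalue(n_pos, n_neg, runs)
    return RANDOM if p >= alpha else TENDENTIOUS


# ---------------------------------------------------------------------------
# fitting


def _rate_param_guess(x: np.ndarray, y: np.ndarray) -> float | None:
    """Log-linear slope estimate of an exponential decay rate, if sensible."""
    mask = (y > 1e-6) & (y <= 1.5) & (x > 0)
    if mask.sum() < 2:
        return None
    slope = np.polyfit(x[mask], -np.log(y[mask]), 1)[0]
    if not np.isfinite(slope) or slope <= 0:
        return None
    return float(slope)


def _initial_vector(
    spec: ModelSpec, x: np.ndarray, y: np.ndarray, init: Mapping[str, float] | None
) -> np.ndarray:
    base = dict(spec.default_init)
    k_guess = _rate_param_guess(x, y)
    if k_guess is not None:
        scale = {"k": 1.0, "k0": 0.6, "k1": 1.6}
        for p in spec.param_names:
            if p in scale:
                base[p] = k_guess * scale[p]
    if init:
        base.update({p: float(v) for p, v in init.items() if p in base})
    lo, hi = spec.bounds_arrays()
    vec = np.array([base[p] for p in spec.param_names])
    return np.clip(vec, lo + 1e-12, hi - 1e-12)


def fit_model(
    x: Sequence[float],
    y: Sequence[float],
    spec: ModelSpec,
    init: Mapping[str, float] | None = None,
    n_starts: int = 8,
    seed: int = 0,
    fixed: Mapping[str, float] | None = None,
    p_threshold: float = 10.0,
) -> FitResult:
    """Fit a registered model by bounded multi-start least squares.

    The first start uses the model's (data-informed) default
    initialisation; subsequent starts apply seeded multiplicative jitter
    U(0.5, 2) per parameter.  The best sum of squared residuals wins.
    Non-convergence of every start is flagged on the result, not raised.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    fixed = dict(fixed or {})
    if x.shape != y.shape or x.ndim != 1:
        raise ContractError("x and y must be 1-D of equal length")
    if not np.all(np.isfinite(y)):
        raise ContractError("y must be finite")
    if np.all(x == x[0]):
        raise ContractError("degenerate predictor: all x equal")
    n = x.size
    p = spec.n_params
    if n < p + 1:
        raise ContractError(f"need at least {p + 1} observations for {spec.name!r}")

    lo, hi = spec.bounds_arrays()
    base = _initial_vector(spec, x, y, init)
    rng = np.random.default_rng(seed)

    def residual(vec: np.ndarray) -> np.ndarray:
        return spec.evaluate_vector(vec, x, **fixed) - y

    best = None
    best_sse = np.inf
    any_success = False
    for s in range(max(1, n_starts)):
        if s == 0:
            start = base
        else:
            jitter = rng.uniform(0.5, 2.0, size=p)
            start = np.where(np.abs(base) > 1e-9, base * jitter,
                             rng.uniform(-0.1, 0.1, size=p))
            start = np.clip(start, lo + 1e-12, hi - 1e-12)
        try:
            sol = least_squares(residual, start, bounds=(lo, hi), method="trf")
        except (ValueError, FloatingPointError):
            continue
        if not np.all(np.isfinite(sol.x)):
            continue
        any_success = any_success or sol.success
        sse = float(2.0 * sol.cost)
        if sse < best_sse:
            best_sse = sse
            best = sol

    if best is None:
        raise ContractError(f"optimiser failed on every start for {spec.name!r}")

    vec = best.x
    yhat = spec.evaluate_vector(vec, x, **fixed)
    resid = y - yhat
    sse = float(np.sum(resid**2))
    glr = n - p
    sstot = float(np.sum((y - y.mean()) ** 2))
    r2 = 100.0 * (1.0 - sse / sstot) if sstot > 0 else np.nan
    se = float(np.sqrt(sse / glr)) if glr >= 1 else np.nan
    p_pct = (
        float(100.0 / n * np.sum(np.abs(resid) / np.abs(y)))
        if np.all(y != 0)
        else np.nan
    )
    try:
        res_class = classify_residuals(resid)
    except ContractError:
        res_class = RANDOM

    at_bounds = tuple(
        name
        for name, v, l, h in zip(spec.param_names, vec, lo, hi)
        if v - l < 1e-8 * max(1.0, abs(l)) + 1e-12
        or h - v < 1e-8 * max(1.0, abs(h)) + 1e-12
    )

    param_se, param_t = _coefficient_tests(best.jac, sse, glr, spec, vec)

    return FitResult(
        model_name=spec.name,
        params={name: float(v) for name, v in zip(spec.param_names, vec)},
        r2_pct=r2,
        se=se,
        p_pct=p_pct,
        residual_class=res_class,
        n_obs=n,
        glr=glr,
        converged=bool(any_success),
        sse=sse,
        at_bounds=at_bounds,
        param_se=param_se,
        param_t=param_t,
    )


def _coefficient_tests(jac, sse, glr, spec, vec):
    """Jacobian-based asymptotic standard errors and t statistics."""
    if glr < 1 or jac is None:
        return {}, {}
    try:
        jtj = jac.T @ jac
        cov = np.linalg.pinv(jtj) * (sse / glr)
        se_vec = np.sqrt(np.clip(np.diag(cov), 0, np.inf))
    except np.linalg.LinAlgError:
        return {}, {}
    p_se = {n: float(s) for n, s in zip(spec.param_names, se_vec)}
    p_t = {
        n: float(v / s) if s > 0 else np.inf
        for n, v, s in zip(spec.param_names, vec, se_vec)
    }
    return p_se, p_t


# ---------------------------------------------------------------------------
# ranking


def _verdict(res: FitResult, p_threshold: float) -> str:
    if res.residual_class != RANDOM:
        return "rejected"
    if not (np.isfinite(res.p_pct) and res.p_pct < p_threshold):
        return "marginal"
    return "acceptable"


def rank_models(
    results: Sequence[FitResult], p_threshold: float = 10.0
) -> list[tuple[FitResult, str]]:
    """Rank fitted models lexicographically and attach a verdict.

    Order: random residuals first, then P below ``p_threshold``, then
    lowest SE, then highest R^2.  All results must come from the same
    data (checked via n_obs).
    """
    if not results:
        raise ContractError("no fit results to rank")
    n_set = {r.n_obs for r in results}
    if len(n_set) > 1:
        raise ContractError("results were fitted to data of differing lengths")

    def key(r: FitResult):
        p_ok = np.isfinite(r.p_pct) and r.p_pct < p_threshold
        se = r.se if np.isfinite(r.se) else np.inf
        r2 = r.r2_pct if np.isfinite(r.r2_pct) else -np.inf
        return (r.residual_class != RANDOM, not p_ok, se, -r2)

    ordered = sorted(results, key=key)
    return [(r, _verdict(r, p_threshold)) for r in ordered]


# ---------------------------------------------------------------------------
# grid-search oracle


def brute_force_fit(
    x: Sequence[float],
    y: Sequence[float],
    spec: ModelSpec,
    step: float = 1e-3,
    bounds: Mapping[str, tuple[float, float]] | None = None,
    n_grid: int = 201,
    fixed: Mapping[str, float] | None = None,
) -> dict[str, float]:
    """Exhaustive zooming grid minimisation of the SSE, for <= 2 parameters.

    Evaluates a full grid over the parameter box, then repeatedly zooms
    onto the best cell until the grid step is below ``step``.  Intended
    as an optimiser-independent oracle for testing, not for routine use.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    fixed = dict(fixed or {})
    if spec.n_params > 2:
        raise ContractError("brute_force_fit supports at most 2 parameters")
    box = {p: tuple(map(float, (bounds or spec.bounds)[p])) for p in spec.param_names}
    for p, (lo, hi) in box.items():
        if not hi > lo:
            raise ContractError(f"degenerate grid bounds for {p!r}")

    names = spec.param_names
    lo = np.array([box[p][0] for p in names])
    hi = np.array([box[p][1] for p in names])
    for _ in range(200):
        axes = [np.linspace(lo[i], hi[i], n_grid) for i in range(len(names))]
        if len(names) == 1:
            grid = axes[0][:, None]
        else:
            g0, g1 = np.meshgrid(axes[0], axes[1], indexing="ij")
            grid = np.column_stack([g0.ravel(), g1.ravel()])
        try:
            # closed forms broadcast: parameter columns against the x row
            cols = [grid[:, j][:, None] for j in range(grid.shape[1])]
            with np.errstate(all="ignore"):
                pred = spec.func(x[None, :], *cols, **fixed)
                sse = np.nansum((pred - y[None, :]) ** 2, axis=1)
                sse[~np.all(np.isfinite(pred), axis=1)] = np.inf
        except Exception:
            sse = np.empty(grid.shape[0])
            for i, vec in enumerate(grid):
                try:
                    pred = spec.evaluate_vector(vec, x, **fixed)
                    sse[i] = np.sum((pred - y) ** 2)
                except Exception:
                    sse[i] = np.inf
        best = grid[int(np.argmin(sse))]
        widths = (hi - lo) / (n_grid - 1)
        if np.all(widths <= step):
            break
        # wide re-grid window: on ridge-shaped SSE surfaces (correlated
        # parameters) the best grid point can sit several cells from the
        # continuous minimiser along the ridge
        lo = np.maximum(lo, best - 10 * widths)
        hi = np.minimum(hi, best + 10 * widths)
    return {p: float(v) for p, v in zip(names, best)}
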