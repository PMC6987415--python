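"""Segmented (broken-line) regression with breakpoint inference.

A model with breakpoints ``psi_1 < ... < psi_B`` is::

    y = b0 + b1 x + sum_k delta_k (x - psi_k)_+ + error

Breakpoints are estimated by iterative linearization: at the current
``psi`` the model is refit with the extra "gap" regressors ``-1(x > psi_k)``
whose coefficients ``gamma_k`` measure the discontinuity the current guess
induces; the update ``psi_k <- psi_k + gamma_k / delta_k`` drives the gaps
to zero.  Convergence is declared when ``max|gamma| < 1e-8 sd(y)``.

Breakpoint existence is tested two ways, both over a fixed grid of candidate
breakpoints (the breakpoint is a nuisance parameter absent under the null):

* Davies' bound on the p-value of the maximal slope-change t statistic;
* a pseudo-score test that averages the hinge regressor over the candidate
  grid and applies an exact F test to the added covariates.

Breakpoint confidence intervals invert a score-type statistic over a dense
candidate grid: a candidate ``psi0`` is retained when the gap coefficient of
a model with the breakpoint pinned at ``psi0`` is not significantly non-zero.
This accommodates the non-smooth, non-concave likelihood in ``psi``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import ndtr

logger = logging.getLogger(__name__)

__all__ = [
    "SegmentedFit",
    "fit_segmented",
    "davies_test",
    "pseudo_score_test",
    "breakpoint_ci",
    "select_n_breakpoints",
]


@dataclass
class SegmentedFit:
    """A fitted piecewise-linear model.

    ``slopes`` lists per-segment slopes (length ``len(breakpoints) + 1``);
    ``slope_changes`` are the hinge coefficients ``delta_k``.  Degrees of
    freedom count ``2 + 2 B`` parameters (intercept, base slope, and one
    slope change plus one breakpoint per break).
    """

    breakpoints: np.ndarray
    intercept: float
    slopes: np.ndarray
    slope_changes: np.ndarray
    x: np.ndarray
    y: np.ndarray
    fitted: np.ndarray
    rss: float
    adjusted_r2: float
    converged: bool
    n_iter: int
    dropped_breakpoints: int = 0
    breakpoint_cis: list[tuple[float, float, float]] | None = None

    @property
    def n_breakpoints(self) -> int:
        return len(self.breakpoints)

    @property
    def r2(self) -> float:
        tss = float(((self.y - self.y.mean()) ** 2).sum())
        return 1.0 - self.rss / tss if tss > 0 else 1.0

    def predict(self, xnew: np.ndarray) -> np.ndarray:
        xnew = np.asarray(xnew, dtype=float)
        out = self.intercept + self.slopes[0] * xnew
        for psi, delta in zip(self.breakpoints, self.slope_changes):
            out = out + delta * np.maximum(xnew - psi, 0.0)
        return out

    def to_dict(self) -> dict:
        return {
            "breakpoints": self.breakpoints.tolist(),
            "intercept": self.intercept,
            "slopes": self.slopes.tolist(),
            "slope_changes": self.slope_changes.tolist(),
            "rss": self.rss,
            "r2": self.r2,
            "adjusted_r2": self.adjusted_r2,
            "converged": self.converged,
            "breakpoint_cis": self.breakpoint_cis,
        }


def _design(x: np.ndarray, psi: np.ndarray, gaps: bool) -> np.ndarray:
    cols = [np.ones_like(x), x]
    cols += [np.maximum(x - p, 0.0) for p in psi]
    if gaps:
        cols += [-(x > p).astype(float) for p in psi]
    return np.column_stack(cols)


def _ols(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return beta


def _adjusted_r2(y: np.ndarray, rss: float, n_params: int) -> float:
    n = y.size
    tss = float(((y - y.mean()) ** 2).sum())
    if tss <= 0:
        return 1.0
    if n - n_params <= 0:
        return -np.inf
    return 1.0 - (rss / (n - n_params)) / (tss / (n - 1))


def fit_segmented(
    x: np.ndarray,
    y: np.ndarray,
    psi0: np.ndarray | list[float],
    fixed_psi: np.ndarray | list[float] | None = None,
    max_iter: int = 100,
    tol: float = 1e-8,
    clamp_percentiles: tuple[float, float] = (2.0, 98.0),
) -> SegmentedFit:
    """Fit a segmented regression of ``y`` on ``x``.

    Parameters
    ----------
    psi0
        Initial breakpoint guesses, strictly inside the data range.
    fixed_psi
        Breakpoints held fixed (not iterated); used e.g. to pin a breakpoint
        at a confidence-interval endpoint while re-estimating the rest.
    clamp_percentiles
        Iterated breakpoints are clamped inside these data percentiles to
        avoid boundary degeneracy.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    psi = np.sort(np.asarray(psi0, dtype=float))
    fixed = np.sort(np.asarray(fixed_psi, dtype=float)) if fixed_psi is not None else np.empty(0)
    n = x.size
    n_free = psi.size
    if n <= 2 + 2 * (n_free + fixed.size):
        raise ValueError("too few points for the requested number of breakpoints")
    lo, hi = x.min(), x.max()
    if ((psi <= lo) | (psi >= hi)).any():
        raise ValueError("initial breakpoints must lie strictly inside the data range")
    clamp_lo, clamp_hi = np.percentile(x, clamp_percentiles)
    sd_y = y.std()
    gamma_tol = tol * (sd_y if sd_y > 0 else 1.0)
    delta_tiny = 1e-12 * max((sd_y if sd_y > 0 else 1.0) / max(x.std(), 1e-30), 1e-30)

    def _rss_at(psi_try: np.ndarray) -> float:
        allp = np.sort(np.concatenate([psi_try, fixed]))
        Xp = _design(x, allp, gaps=False)
        return float(((y - Xp @ _ols(Xp, y)) ** 2).sum())

    converged = sd_y == 0
    it = 0
    dropped = 0
    rss_cur = _rss_at(psi) if psi.size else np.inf
    while psi.size and not converged and it < max_iter:
        it += 1
        all_psi = np.sort(np.concatenate([psi, fixed]))
        X = np.column_stack(
            [np.ones_like(x), x]
            + [np.maximum(x - p, 0.0) for p in all_psi]
            + [-(x > p).astype(float) for p in psi]
        )
        beta = _ols(X, y)
        # hinge coefs for the free psi occupy positions matching their sorted slot
        order = np.searchsorted(all_psi, psi)
        delta = beta[2 + order]
        gamma = beta[2 + all_psi.size :]
        if np.max(np.abs(gamma)) < gamma_tol:
            converged = True
            break
        keep = np.abs(delta) > delta_tiny
        if not keep.all():
            dropped += int((~keep).sum())
            warnings.warn(
                f"dropping {int((~keep).sum())} breakpoint(s) with vanishing slope change",
                RuntimeWarning,
                stacklevel=2,
            )
            psi = psi[keep]
            delta, gamma = delta[keep], gamma[keep]
            if psi.size == 0:
                break
        # damped update: halve the step until the segmented RSS improves,
        # preventing the oscillation the raw update is prone to
        step = gamma / delta
        accepted = False
        for _ in range(12):
            psi_try = np.sort(np.clip(psi + step, clamp_lo, clamp_hi))
            rss_try = _rss_at(psi_try)
            if rss_try <= rss_cur + 1e-12 * max(rss_cur, 1.0):
                move = np.max(np.abs(psi_try - np.sort(psi)))
                psi, rss_cur = psi_try, rss_try
                accepted = True
                if move < 1e-9 * max(hi - lo, 1e-300):
                    converged = True
                break
            step = step / 2.0
        if not accepted:
            converged = True  # no improving step remains: at a fixed point
        # merge breakpoints that collapsed onto each other
        if psi.size > 1:
            distinct = np.concatenate([[True], np.diff(psi) > 1e-10 * (hi - lo)])
            if not distinct.all():
                dropped += int((~distinct).sum())
                warnings.warn("merging coincident breakpoints", RuntimeWarning, stacklevel=2)
                psi = psi[distinct]
                rss_cur = _rss_at(psi) if psi.size else np.inf

    all_psi = np.sort(np.concatenate([psi, fixed]))
    X = _design(x, all_psi, gaps=False)
    beta = _ols(X, y)
    fittedv = X @ beta
    rss = float(((y - fittedv) ** 2).sum())
    slope_changes = beta[2:]
    slopes = np.concatenate([[beta[1]], beta[1] + np.cumsum(slope_changes)])
    n_params = 2 + 2 * all_psi.size
    return SegmentedFit(
        breakpoints=all_psi,
        intercept=float(beta[0]),
        slopes=slopes,
        slope_changes=np.asarray(slope_changes),
        x=x,
        y=y,
        fitted=fittedv,
        rss=rss,
        adjusted_r2=_adjusted_r2(y, rss, n_params),
        converged=bool(converged or psi.size == 0),
        n_iter=it,
        dropped_breakpoints=dropped,
    )


def _candidate_grid(x: np.ndarray, k: int) -> np.ndarray:
    return np.linspace(x.min(), x.max(), k + 2)[1:-1]


def _slope_change_tstats(x: np.ndarray, y: np.ndarray, candidates: np.ndarray) -> np.ndarray:
    """t statistic of the hinge coefficient at each candidate breakpoint."""
    n = x.size
    out = np.empty(candidates.size)
    for i, c in enumerate(candidates):
        X = np.column_stack([np.ones_like(x), x, np.maximum(x - c, 0.0)])
        beta, res, rank, _ = np.linalg.lstsq(X, y, rcond=None)
        fittedv = X @ beta
        rss = float(((y - fittedv) ** 2).sum())
        dof = n - 3
        sigma2 = rss / dof if dof > 0 else np.nan
        XtX_inv = np.linalg.pinv(X.T @ X)
        se = np.sqrt(max(sigma2 * XtX_inv[2, 2], 1e-300))
        out[i] = beta[2] / se
    return out


def davies_test(x: np.ndarray, y: np.ndarray, k: int = 10) -> float:
    """Two-sided Davies bound for a slope change at an unknown breakpoint.

    The slope-change t statistic is evaluated at ``k`` evenly spaced interior
    candidates; the p-value of its maximal magnitude is bounded using the
    total variation of the statistic process::

        p <= 2 Phi(-M) + V exp(-M^2 / 2) / sqrt(8 pi)

    with ``M = max |t|`` and ``V = sum |t_{i+1} - t_i|``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 10:
        raise ValueError("davies_test needs n >= 10")
    if x.std() == 0:
        raise ValueError("constant x")
    s = _slope_change_tstats(x, y, _candidate_grid(x, k))
    M = float(np.max(np.abs(s)))
    V = float(np.sum(np.abs(np.diff(s))))
    p = 2.0 * ndtr(-M) + V * np.exp(-0.5 * M * M) / np.sqrt(8.0 * np.pi)
    return float(min(max(p, np.finfo(float).tiny), 1.0))


def pseudo_score_test(
    x: np.ndarray, y: np.ndarray, n_breakpoints: int = 1, k: int = 10
) -> float:
    """Score-type breakpoint test aggregating hinge regressors over a grid.

    The ``k`` candidate hinges are split into ``n_breakpoints`` contiguous
    groups and averaged, giving fixed pseudo-covariates whose joint
    significance over the straight-line null is assessed with an exact
    F test (t test when ``n_breakpoints == 1``).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 10:
        raise ValueError("pseudo_score_test needs n >= 10")
    if x.std() == 0:
        raise ValueError("constant x")
    candidates = _candidate_grid(x, k)
    groups = np.array_split(candidates, n_breakpoints)
    Z = np.column_stack(
        [np.mean([np.maximum(x - c, 0.0) for c in g], axis=0) for g in groups]
    )
    X0 = np.column_stack([np.ones_like(x), x])
    X1 = np.column_stack([X0, Z])
    rss0 = float(((y - X0 @ _ols(X0, y)) ** 2).sum())
    rss1 = float(((y - X1 @ _ols(X1, y)) ** 2).sum())
    q = Z.shape[1]
    dof = n - 2 - q
    if dof <= 0:
        raise ValueError("too few points for the pseudo-score test")
    if rss1 <= 0:
        return float(np.finfo(float).tiny)
    F = ((rss0 - rss1) / q) / (rss1 / dof)
    return float(max(stats.f.sf(F, q, dof), np.finfo(float).tiny))


def breakpoint_ci(
    fit: SegmentedFit, level: float = 0.95, grid_size: int = 100
) -> list[tuple[float, float, float]]:
    """Score-inversion confidence interval for each breakpoint.

    Candidates span the stretch between the neighbouring breakpoints (or the
    data range).  A candidate ``psi0`` is accepted when, pinning the
    breakpoint there (other breakpoints held at their estimates), the gap
    coefficient's |t| stays below the two-sided critical value.  The interval
    is the hull of accepted candidates and always contains the estimate.
    Results are stored on ``fit.breakpoint_cis`` and returned.
    """
    if not fit.converged:
        raise ValueError("confidence intervals require a converged fit")
    x, y = fit.x, fit.y
    n = x.size
    psi_hat = fit.breakpoints
    cis: list[tuple[float, float, float]] = []
    lo, hi = x.min(), x.max()
    bounds = np.concatenate([[lo], psi_hat, [hi]])
    for b, psi_b in enumerate(psi_hat):
        grid = np.linspace(bounds[b], bounds[b + 2], grid_size + 2)[1:-1]
        others = np.delete(psi_hat, b)
        n_params = 2 + len(psi_hat) + len(psi_hat)  # hinges for all + one gap
        dof = n - (3 + len(psi_hat))
        crit = stats.t.ppf(0.5 + level / 2.0, dof)
        tvals = np.zeros(grid.size)
        for gi, c in enumerate(grid):
            cols = [np.ones_like(x), x]
            cols += [np.maximum(x - p, 0.0) for p in np.sort(np.append(others, c))]
            cols.append(-(x > c).astype(float))
            X = np.column_stack(cols)
            beta = _ols(X, y)
            rss = float(((y - X @ beta) ** 2).sum())
            sigma2 = rss / dof if dof > 0 else np.nan
            XtX_inv = np.linalg.pinv(X.T @ X)
            se = np.sqrt(max(sigma2 * XtX_inv[-1, -1], 0.0))
            tvals[gi] = beta[-1] / se if se > 0 else 0.0
        accept = np.abs(tvals) <= crit
        # the interval is the connected acceptance run containing the
        # estimate (the hull of all accepted candidates would over-cover
        # when disjoint acceptance pockets exist elsewhere in the range),
        # with the endpoints interpolated to the |t| = crit crossings
        anchor = int(np.argmin(np.abs(grid - psi_b)))
        lo_i = anchor
        while lo_i > 0 and accept[lo_i - 1]:
            lo_i -= 1
        hi_i = anchor
        while hi_i < grid.size - 1 and accept[hi_i + 1]:
            hi_i += 1
        if accept[anchor]:
            lo_b, hi_b = grid[lo_i], grid[hi_i]
            if lo_i > 0:
                a0, a1 = abs(tvals[lo_i - 1]), abs(tvals[lo_i])
                frac = (a0 - crit) / (a0 - a1) if a0 != a1 else 0.0
                lo_b = grid[lo_i - 1] + frac * (grid[lo_i] - grid[lo_i - 1])
            if hi_i < grid.size - 1:
                a0, a1 = abs(tvals[hi_i]), abs(tvals[hi_i + 1])
                frac = (crit - a0) / (a1 - a0) if a0 != a1 else 0.0
                hi_b = grid[hi_i] + frac * (grid[hi_i + 1] - grid[hi_i])
        else:
            lo_b = hi_b = psi_b
        cis.append((min(lo_b, psi_b), max(hi_b, psi_b), level))
    fit.breakpoint_cis = cis
    return cis


def select_n_breakpoints(
    x: np.ndarray,
    y: np.ndarray,
    max_breaks: int = 4,
    tie_tol: float = 1e-4,
) -> tuple[SegmentedFit, pd.DataFrame]:
    """Fit 1..max_breaks breakpoints and pick the best by adjusted R^2.

    Initial breakpoints are quantile-spaced.  Ties within ``tie_tol`` of the
    maximum adjusted R^2 resolve to the fewest breakpoints (parsimony).
    Returns ``(best_fit, table)`` with one table row per candidate.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    rows = []
    fits: dict[int, SegmentedFit] = {}
    for b in range(1, max_breaks + 1):
        psi0 = np.quantile(x, (np.arange(1, b + 1)) / (b + 1))
        # nudge quantile-coincident guesses apart
        psi0 = np.unique(psi0)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                fit = fit_segmented(x, y, psi0)
            fits[b] = fit
            rows.append(
                {
                    "n_breakpoints": b,
                    "n_estimated": fit.n_breakpoints,
                    "adjusted_r2": fit.adjusted_r2,
                    "rss": fit.rss,
                    "converged": fit.converged,
                }
            )
        except Exception as err:  # recorded, not fatal
            logger.warning("segmented fit with %d breakpoints failed: %s", b, err)
            rows.append(
                {
                    "n_breakpoints": b,
                    "n_estimated": np.nan,
                    "adjusted_r2": np.nan,
                    "rss": np.nan,
                    "converged": False,
                }
            )
    table = pd.DataFrame(rows).set_index("n_breakpoints")
    if not fits:
        raise RuntimeError("all segmented candidates failed")
    best_r2 = max(f.adjusted_r2 for f in fits.values())
    best_b = min(b for b, f in fits.items() if f.adjusted_r2 >= best_r2 - tie_tol)
    return fits[best_b], table
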