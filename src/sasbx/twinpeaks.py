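"""Twin-Peaks curve fitting and resampling inference.

Divergence is regressed on the expression-bias statistic Δ with
polynomials (each population's per-gene value is a replicate row).  The
"Twin Peaks" pattern -- divergence minimal at Δ = 0 and at complete bias,
maximal at intermediate |Δ| -- is operationalised on a quartic fit by
three criteria:

  1. the overall regression is significant (ANOVA F-test, p < 0.05);
  2. the leading (quartic) coefficient is negative;
  3. the derivative has three distinct real roots in [-1, 1]
     (two local maxima flanking a local minimum).

Significance of an observed pattern comes from a permutation test (Δ
labels shuffled, quartic refit, criteria re-evaluated); uncertainty in
the fitted curve and in the peak/valley locations comes from a bootstrap
over genes.  A binary-response variant fits the probability that a gene
is under sexually-antagonistic selection as a function of Δ (logistic
polynomial plus a binned-proportion quartic).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import cho_factor, cho_solve
from sklearn.base import BaseEstimator, RegressorMixin

logger = logging.getLogger(__name__)

#: a derivative root counts as real iff |Im| < this times (1 + |Re|)
IMAG_TOL = 1e-8
#: roots closer than this (relative) are one distinct root (multiplicity)
DEDUPE_TOL = 1e-6


# ---------------------------------------------------------------------------
# basic least-squares machinery

def _design(delta: np.ndarray, degree: int) -> np.ndarray:
    return np.vander(np.asarray(delta, dtype=float), degree + 1, increasing=True)


def _ols(delta, response, degree):
    """Least-squares polynomial fit with overall F-test and Gaussian AIC."""
    y = np.asarray(response, dtype=float)
    V = _design(delta, degree)
    if np.linalg.matrix_rank(V) < V.shape[1]:
        raise np.linalg.LinAlgError("rank-deficient polynomial design")
    beta, _, _, _ = np.linalg.lstsq(V, y, rcond=None)
    resid = y - V @ beta
    rss = float(resid @ resid)
    tss = float(np.sum((y - y.mean()) ** 2))
    n, k = len(y), degree
    if k == 0 or tss <= 0:
        p_anova = 1.0
    else:
        df_resid = n - k - 1
        f = ((tss - rss) / k) / (rss / df_resid) if rss > 0 else np.inf
        p_anova = float(stats.f.sf(f, k, df_resid))
    # Gaussian log-likelihood; +1 free parameter for the error variance
    ll = -0.5 * n * (np.log(2.0 * np.pi * max(rss, 1e-300) / n) + 1.0)
    aic = 2.0 * (degree + 2) - 2.0 * ll
    return beta, p_anova, aic, rss


def _distinct_real_roots(coefs_ascending, interval=(-1.0, 1.0)):
    """Distinct real roots of a polynomial inside a closed interval.

    Roots are taken from the companion matrix (np.roots); near-equal roots
    (multiplicity) collapse to a single distinct root.
    """
    c = np.asarray(coefs_ascending, dtype=float)
    c = np.trim_zeros(c, "b")
    if c.size <= 1:
        return np.array([])
    roots = np.roots(c[::-1])
    real = roots[np.abs(roots.imag) < IMAG_TOL * (1.0 + np.abs(roots.real))].real
    real = np.sort(real[(real >= interval[0]) & (real <= interval[1])])
    distinct = []
    for r in real:
        if not distinct or abs(r - distinct[-1]) > DEDUPE_TOL * (1.0 + abs(r)):
            distinct.append(r)
    return np.asarray(distinct)


def _poly_derivative(coefs_ascending) -> np.ndarray:
    c = np.asarray(coefs_ascending, dtype=float)
    return c[1:] * np.arange(1, len(c))


def peak_locations(coefs_ascending, interval=(-1.0, 1.0)):
    """Local maxima and minima of a polynomial inside an interval.

    Stationary points are real derivative roots in the interval, classified
    by the sign of the second derivative (inflections are neither).
    Returns ``(maxima, minima)``, each sorted ascending.
    """
    c = np.asarray(coefs_ascending, dtype=float)
    if len(c) - 1 < 2:
        raise ValueError("peak_locations requires degree >= 2")
    d1 = _poly_derivative(c)
    d2 = _poly_derivative(d1)
    crit = _distinct_real_roots(d1, interval)
    curv = np.polyval(d2[::-1], crit) if crit.size else np.array([])
    return crit[curv < 0], crit[curv > 0]


@dataclass
class TwinPeaksFit:
    """A polynomial fit of divergence on Δ plus the Twin-Peaks criteria."""

    degree: int
    coefficients: np.ndarray  # ascending powers
    p_anova: float
    aic: float
    leading_negative: bool
    derivative_real_roots_in_range: int
    is_twin_peaks: bool | None
    peak_locations: np.ndarray
    valley_location: float | None

    def predict(self, delta):
        return np.polyval(self.coefficients[::-1], np.asarray(delta, dtype=float))


def detect_twin_peaks(fit: TwinPeaksFit, interval=(-1.0, 1.0), alpha: float = 0.05) -> bool:
    """Apply the three Twin-Peaks criteria to a quartic fit."""
    if fit.degree != 4:
        raise ValueError("Twin-Peaks criteria are defined for a quartic fit")
    roots = _distinct_real_roots(_poly_derivative(fit.coefficients), interval)
    return bool(fit.p_anova < alpha and fit.coefficients[4] < 0 and len(roots) == 3)


def fit_polynomial(delta, response, degree: int, interval=(-1.0, 1.0),
                   alpha: float = 0.05) -> TwinPeaksFit:
    """Fit response on powers of Δ and evaluate the Twin-Peaks criteria.

    Requires at least degree + 2 distinct Δ values.  The criteria flags are
    always recorded; ``is_twin_peaks`` is meaningful (non-None) only for
    degree 4.
    """
    delta = np.asarray(delta, dtype=float)
    if len(np.unique(delta)) < degree + 2:
        raise ValueError(f"need at least {degree + 2} distinct delta values")
    beta, p_anova, aic, _ = _ols(delta, response, degree)
    n_roots = len(_distinct_real_roots(_poly_derivative(beta), interval)) if degree >= 1 else 0
    maxima, minima = (peak_locations(beta, interval) if degree >= 2
                      else (np.array([]), np.array([])))
    fit = TwinPeaksFit(
        degree=degree,
        coefficients=beta,
        p_anova=p_anova,
        aic=aic,
        leading_negative=bool(beta[-1] < 0),
        derivative_real_roots_in_range=n_roots,
        is_twin_peaks=None,
        peak_locations=maxima,
        valley_location=float(minima[0]) if len(minima) == 1 else
        (float(minima[len(minima) // 2]) if len(minima) else None),
    )
    if degree == 4:
        fit.is_twin_peaks = detect_twin_peaks(fit, interval, alpha)
    return fit


def select_degree(delta, response, max_degree: int = 6):
    """Pick the polynomial degree by AIC (ties resolved to the lower degree).

    Returns ``(degree, table)`` where the table lists AIC per degree and
    the nested likelihood-ratio F-test of each degree against the next.
    """
    delta = np.asarray(delta, dtype=float)
    y = np.asarray(response, dtype=float)
    n = len(y)
    rows = []
    fits = {}
    for d in range(max_degree + 1):
        beta, p_anova, aic, rss = _ols(delta, y, d)
        fits[d] = (beta, rss)
        rows.append({"degree": d, "aic": aic, "p_anova": p_anova, "rss": rss})
    table = pd.DataFrame(rows)
    lrt_p = [np.nan]
    for d in range(1, max_degree + 1):
        rss0, rss1 = fits[d - 1][1], fits[d][1]
        df_resid = n - d - 1
        f = (rss0 - rss1) / (rss1 / df_resid) if rss1 > 0 else np.inf
        lrt_p.append(float(stats.f.sf(f, 1, df_resid)))
    table["lrt_p_vs_lower"] = lrt_p
    best = int(table.loc[table["aic"].idxmin(), "degree"])  # idxmin: first minimum
    return best, table


class TwinPeaksRegressor(RegressorMixin, BaseEstimator):
    """Polynomial regression of divergence on Δ with Twin-Peaks detection.

    scikit-learn estimator: ``fit(X, y)`` with X the Δ values (shape (n,)
    or (n, 1)) and y the per-gene divergence response.

    Parameters
    ----------
    degree : int or "auto"
        Polynomial degree; "auto" selects by AIC up to ``max_degree``.
    max_degree : int
    alpha : float
        Significance level for the ANOVA criterion.
    interval : pair of floats
        Range inside which derivative roots are counted.

    Attributes
    ----------
    degree_ : selected degree
    coef_ : ascending polynomial coefficients
    p_anova_, aic_ : overall-fit statistics
    leading_negative_, n_derivative_roots_, is_twin_peaks_ : criteria
    peaks_, valley_ : stationary-point locations in the interval
    selection_table_ : AIC/LRT table (only when degree="auto")
    """

    def __init__(self, degree="auto", max_degree: int = 6, alpha: float = 0.05,
                 interval=(-1.0, 1.0)):
        self.degree = degree
        self.max_degree = max_degree
        self.alpha = alpha
        self.interval = interval

    @staticmethod
    def _as_delta(X):
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            if X.shape[1] != 1:
                raise ValueError("X must have a single Δ column")
            X = X[:, 0]
        return X

    def fit(self, X, y):
        delta = self._as_delta(X)
        y = np.asarray(y, dtype=float)
        if self.degree == "auto":
            self.degree_, self.selection_table_ = select_degree(delta, y, self.max_degree)
        else:
            self.degree_ = int(self.degree)
        f = fit_polynomial(delta, y, self.degree_, self.interval, self.alpha)
        self.fit_ = f
        self.coef_ = f.coefficients
        self.p_anova_ = f.p_anova
        self.aic_ = f.aic
        self.leading_negative_ = f.leading_negative
        self.n_derivative_roots_ = f.derivative_real_roots_in_range
        self.is_twin_peaks_ = bool(f.is_twin_peaks) if f.is_twin_peaks is not None else False
        self.peaks_ = f.peak_locations
        self.valley_ = f.valley_location
        return self

    def predict(self, X):
        return np.polyval(self.coef_[::-1], self._as_delta(X))


# ---------------------------------------------------------------------------
# resampling inference

@dataclass
class ResamplingResult:
    """Permutation or bootstrap summary for the Twin-Peaks criteria."""

    n_replicates: int
    pattern_count: int
    p_value: float
    seed: int
    peak_location_ci: dict | None = None
    curve_density: dict | None = None
    n_failed: int = 0
    replicate_coefficients: np.ndarray | None = field(default=None, repr=False)


def _criteria_from_beta(beta, p_anova, interval, alpha):
    if not (p_anova < alpha and beta[4] < 0):
        return False
    return len(_distinct_real_roots(_poly_derivative(beta), interval)) == 3


def permutation_test(delta, response, n_perm: int, seed: int,
                     alpha: float = 0.05, interval=(-1.0, 1.0)) -> ResamplingResult:
    """Permutation null for the Twin-Peaks pattern.

    Δ labels are shuffled across all rows, a quartic is refit, and the
    three criteria are re-evaluated; the p-value is the continuity-
    corrected fraction (count + 1)/(n_perm + 1) of permutations showing
    the pattern.

    Permuting Δ rows leaves the Gram matrix of the quartic design
    unchanged, so each permutation costs one 5-vector projection and a
    5x5 solve.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    delta = np.asarray(delta, dtype=float)
    y = np.asarray(response, dtype=float)
    n = len(y)
    V = _design(delta, 4)
    G = V.T @ V
    cho = cho_factor(G)
    yy = float(y @ y)
    tss = float(np.sum((y - y.mean()) ** 2))
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        yp = y[rng.permutation(n)]
        vty = V.T @ yp
        beta = cho_solve(cho, vty)
        rss = max(yy - float(beta @ vty), 0.0)
        df_resid = n - 5
        f = ((tss - rss) / 4.0) / (rss / df_resid) if rss > 0 else np.inf
        p_anova = float(stats.f.sf(f, 4, df_resid))
        if _criteria_from_beta(beta, p_anova, interval, alpha):
            count += 1
    return ResamplingResult(
        n_replicates=n_perm,
        pattern_count=count,
        p_value=(count + 1) / (n_perm + 1),
        seed=seed,
    )


def bootstrap_curves(delta, response, gene_ids, n_boot: int, seed: int,
                     alpha: float = 0.05, interval=(-1.0, 1.0),
                     grid_points: int = 101, density_bins: int = 64) -> ResamplingResult:
    """Bootstrap the quartic fit by resampling genes with replacement.

    Genes (not gene x population rows) are the resampling unit, respecting
    within-gene correlation across populations.  Records the fraction of
    replicates meeting the three criteria, percentile CIs of the two peak
    locations and the valley, and a gridded density of the fitted curves
    over Δ in [-1, 1] (the heat-map surface).  Rank-deficient replicates
    are skipped and counted.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    delta = np.asarray(delta, dtype=float)
    y = np.asarray(response, dtype=float)
    codes, uniques = pd.factorize(np.asarray(gene_ids))
    order = np.argsort(codes, kind="stable")
    sorted_codes = codes[order]
    starts = np.searchsorted(sorted_codes, np.arange(len(uniques)))
    ends = np.searchsorted(sorted_codes, np.arange(len(uniques)), side="right")
    gene_rows = [order[s:e] for s, e in zip(starts, ends)]

    V = _design(delta, 4)
    rng = np.random.default_rng(seed)
    grid = np.linspace(interval[0], interval[1], grid_points)
    Vg = np.vander(grid, 5, increasing=True)

    coefs, met, failed = [], 0, 0
    left_peaks, right_peaks, valleys = [], [], []
    for _ in range(n_boot):
        sampled = rng.integers(0, len(uniques), size=len(uniques))
        rows = np.concatenate([gene_rows[g] for g in sampled])
        Vb, yb = V[rows], y[rows]
        G = Vb.T @ Vb
        try:
            cho = cho_factor(G)
        except np.linalg.LinAlgError:
            failed += 1
            continue
        vty = Vb.T @ yb
        beta = cho_solve(cho, vty)
        rss = max(float(yb @ yb) - float(beta @ vty), 0.0)
        tss = float(np.sum((yb - yb.mean()) ** 2))
        df_resid = len(yb) - 5
        f = ((tss - rss) / 4.0) / (rss / df_resid) if rss > 0 else np.inf
        p_anova = float(stats.f.sf(f, 4, df_resid))
        coefs.append(beta)
        if _criteria_from_beta(beta, p_anova, interval, alpha):
            met += 1
        maxima, minima = peak_locations(beta, interval)
        if len(maxima) == 2:
            left_peaks.append(maxima[0])
            right_peaks.append(maxima[1])
            if len(minima) >= 1:
                valleys.append(minima[np.argmin(np.abs(minima - maxima.mean()))])
    if failed:
        logger.warning("%d of %d bootstrap replicates rank-deficient, skipped", failed, n_boot)

    coefs = np.asarray(coefs)
    density = None
    if len(coefs):
        curves = coefs @ Vg.T  # (replicates, grid)
        lo, hi = np.percentile(curves, [1, 99])
        if hi <= lo:
            hi = lo + 1e-12
        edges = np.linspace(lo, hi, density_bins + 1)
        dens = np.stack([np.histogram(curves[:, j], bins=edges)[0] for j in range(grid_points)], axis=1)
        density = {"delta_grid": grid, "response_edges": edges,
                   "density": dens / max(len(coefs), 1)}

    def _ci(vals):
        if not vals:
            return None
        lo_, hi_ = np.percentile(vals, [2.5, 97.5])
        return (float(lo_), float(hi_))

    n_ok = len(coefs)
    return ResamplingResult(
        n_replicates=n_ok,
        pattern_count=met,
        p_value=(met + 1) / (n_ok + 1),  # corrected fraction meeting the pattern
        seed=seed,
        peak_location_ci={"left_peak": _ci(left_peaks), "right_peak": _ci(right_peaks),
                          "valley": _ci(valleys)},
        curve_density=density,
        n_failed=failed,
        replicate_coefficients=coefs,
    )


def quadratic_small_delta(delta, response, window=(-0.52, 0.72)):
    """Quadratic fit restricted to weakly biased genes (Δ inside ``window``).

    The small-bias model predicts divergence = const + 4·mean(pq)·A·Δ², so
    a significantly positive quadratic coefficient is the model check.
    Returns a dict with the coefficient, its SE and p-value, and the
    fraction of rows inside the window.
    """
    if not (-1.0 <= window[0] < window[1] <= 1.0):
        raise ValueError("window must be an interval inside [-1, 1]")
    delta = np.asarray(delta, dtype=float)
    y = np.asarray(response, dtype=float)
    mask = (delta > window[0]) & (delta < window[1])
    if mask.sum() < 10:
        raise ValueError("fewer than 10 observations inside the window")
    import statsmodels.api as sm

    V = _design(delta[mask], 2)
    res = sm.OLS(y[mask], V).fit()
    return {
        "quadratic_coefficient": float(res.params[2]),
        "se": float(res.bse[2]),
        "p_value": float(res.pvalues[2]),
        "fraction_in_window": float(mask.mean()),
        "n_in_window": int(mask.sum()),
    }


@dataclass
class BinaryResponseFit:
    """Twin-Peaks analysis of a binary selection indicator vs Δ."""

    logistic_degree: int
    logistic_coefficients: np.ndarray
    logistic_aic: float
    binned_fit: TwinPeaksFit
    bin_deltas: np.ndarray
    bin_proportions: np.ndarray
    is_twin_peaks: bool

    def predict_probability(self, delta):
        eta = np.polyval(self.logistic_coefficients[::-1], np.asarray(delta, dtype=float))
        return 1.0 / (1.0 + np.exp(-eta))


def binary_response_fit(delta, response, max_degree: int = 6,
                        n_bins: int = 25, alpha: float = 0.05,
                        interval=(-1.0, 1.0)) -> BinaryResponseFit:
    """Fit P(under selection | Δ) for a strictly binary response.

    Two parallel routes: a logistic regression on polynomial terms of Δ
    (degree chosen by AIC), and proportions in ``n_bins`` equal-count Δ
    bins followed by a quartic fit; the Twin-Peaks criteria are applied to
    the binned-proportion quartic.
    """
    import statsmodels.api as sm

    delta = np.asarray(delta, dtype=float)
    y = np.asarray(response, dtype=float)
    uniq = np.unique(y)
    if not np.all(np.isin(uniq, [0.0, 1.0])):
        raise ValueError("response must be binary (0/1)")
    if len(uniq) < 2:
        raise ValueError("response is constant (all 0 or all 1)")

    best = None
    for d in range(1, max_degree + 1):
        V = _design(delta, d)
        try:
            res = sm.GLM(y, V, family=sm.families.Binomial()).fit()
        except Exception:  # separation / convergence failure at high degree
            continue
        if best is None or res.aic < best[2]:
            best = (d, np.asarray(res.params), float(res.aic))
    if best is None:
        raise RuntimeError("logistic fit failed at every degree")

    order = np.argsort(delta, kind="stable")
    chunks = np.array_split(order, n_bins)
    bin_d = np.array([delta[c].mean() for c in chunks])
    bin_p = np.array([y[c].mean() for c in chunks])
    binned = fit_polynomial(bin_d, bin_p, 4, interval, alpha)
    return BinaryResponseFit(
        logistic_degree=best[0],
        logistic_coefficients=best[1],
        logistic_aic=best[2],
        binned_fit=binned,
        bin_deltas=bin_d,
        bin_proportions=bin_p,
        is_twin_peaks=bool(binned.is_twin_peaks),
    )


def geneset_permutation(gene_values: pd.Series, set_ids, n_perm: int, seed: int) -> float:
    """One-sided permutation p for a gene set's mean exceeding random sets.

    ``gene_values`` is a per-gene statistic indexed by gene id.  The p-value
    is (count of random same-size subsets with mean >= observed + 1) /
    (n_perm + 1).
    """
    values = gene_values.to_numpy(dtype=float)
    set_ids = list(set_ids)
    missing = [g for g in set_ids if g not in gene_values.index]
    if missing:
        raise KeyError(f"gene ids not found: {missing[:10]}")
    if len(set_ids) == 0 or len(set_ids) >= len(gene_values):
        raise ValueError("subset must be non-empty and smaller than the table")
    observed = float(gene_values.loc[set_ids].mean())
    rng = np.random.default_rng(seed)
    k = len(set_ids)
    count = 0
    for _ in range(n_perm):
        idx = rng.choice(len(values), size=k, replace=False)
        if values[idx].mean() >= observed:
            count += 1
    return (count + 1) / (n_perm + 1)


def spline_curve(delta, response, grid=None, n_bins: int = 200):
    """Penalized cubic smoothing-spline alternative to the quartic.

    Replicate rows are first reduced to equal-count Δ-bin means (the
    smoother needs strictly increasing abscissae); the smoothing parameter
    is chosen by generalized cross-validation.  Reported alongside the
    polynomial fit; never used for the Twin-Peaks criteria.
    """
    from scipy.interpolate import make_smoothing_spline

    delta = np.asarray(delta, dtype=float)
    y = np.asarray(response, dtype=float)
    order = np.argsort(delta, kind="stable")
    n_bins = min(n_bins, max(len(y) // 2, 4))
    chunks = np.array_split(order, n_bins)
    bx = np.array([delta[c].mean() for c in chunks])
    by = np.array([y[c].mean() for c in chunks])
    bx, keep = np.unique(bx, return_index=True)
    by = by[keep]
    spl = make_smoothing_spline(bx, by)
    if grid is None:
        grid = np.linspace(bx[0], bx[-1], 201)
    return grid, spl(grid)
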