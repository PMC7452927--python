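"""Model diagnostics: eta-sampling GAM ICC checks, VPCs, residual correlations.

The GAM ICC check addresses a known weakness of empirical-Bayes-based
diagnostics: shrinkage of the disability estimates can make an adequate
model look inadequate, especially at extreme disability.  Instead of
smoothing against the point estimates, the check draws many samples from
each pseudo-individual's posterior (normal with the MAP estimate as mean and
the curvature-based variance), maps them to the disability scale respecting
the baseline/post-baseline origin, and fits a cross-validated cubic-spline
smooth of each cumulative score indicator against the sampled disability.
Because the sampling inflates the apparent number of observations, the
smooth's standard error is multiplied by the square root of the number of
samples per pseudo-individual, so the confidence band reflects the real
amount of data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline
from scipy.stats import norm

from .grm import ItemBank, cumulative_probability, expected_score
from .icc import ITEM_COLS, reshape_idvis

__all__ = [
    "GamCheckResult",
    "VpcResult",
    "sampled_gam_icc_check",
    "residual_correlation",
    "vpc",
]


# ---------------------------------------------------------------------------
# penalised cubic spline with GCV (a P-spline smoother)


class _GcvLogisticSpline:
    """Cross-validated cubic-spline logistic smoother for binary indicators.

    A P-spline: cubic B-spline basis (dimension ~10, knots at data
    quantiles) with a second-difference coefficient penalty, fitted by
    penalised IRLS on the binomial likelihood.  The penalty weight is chosen
    by generalised cross-validation on the deviance,
    ``n * Dev / (n - tr(S))^2``.  Observations are first aggregated into
    fine x-bins with binomial counts, which leaves the likelihood of the
    smooth essentially unchanged while keeping the cost independent of the
    number of posterior samples.

    Confidence bands are computed on the linear-predictor scale from the
    sandwich covariance of the penalised fit and mapped through the inverse
    logit.
    """

    def __init__(self, n_basis: int = 10, degree: int = 3, n_bins: int = 400):
        self.n_basis = n_basis
        self.degree = degree
        self.n_bins = n_bins

    def fit(self, x, y, alphas=None):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        # aggregate to binomial counts on an x-quantile grid
        edges = np.unique(np.quantile(x, np.linspace(0, 1, self.n_bins + 1)))
        idx = np.clip(np.searchsorted(edges, x, side="right") - 1, 0, edges.size - 2)
        m = np.bincount(idx, minlength=edges.size - 1).astype(float)
        s = np.bincount(idx, weights=y, minlength=edges.size - 1)
        xs = np.bincount(idx, weights=x, minlength=edges.size - 1)
        keep = m > 0
        m, s = m[keep], s[keep]
        xb = xs[keep] / m

        k, deg = self.n_basis, self.degree
        inner = np.unique(np.quantile(x, np.linspace(0, 1, k - deg + 1)))
        lo, hi = inner[0] - 1e-6, inner[-1] + 1e-6
        t = np.concatenate([[lo] * deg, inner, [hi] * deg])
        self._knots = t
        B = BSpline.design_matrix(np.clip(xb, lo, hi), t, deg).toarray()
        k = B.shape[1]
        D = np.diff(np.eye(k), n=2, axis=0)
        P = D.T @ D
        n = float(m.sum())
        if alphas is None:
            alphas = np.logspace(-4, 6, 21) * n / k
        p0 = np.clip(s.sum() / n, 1e-6, 1 - 1e-6)
        best = None
        for a in alphas:
            beta, ok = self._irls(B, P, m, s, a, np.log(p0 / (1 - p0)))
            if not ok:
                continue
            eta = B @ beta
            p = _expit(eta)
            dev = 2.0 * np.sum(
                s * np.log(np.maximum(s, 1e-12) / np.maximum(m * p, 1e-300))
                + (m - s)
                * np.log(np.maximum(m - s, 1e-12) / np.maximum(m * (1 - p), 1e-300))
            )
            w = m * np.maximum(p * (1 - p), 1e-10)
            BtWB = B.T @ (B * w[:, None])
            Ainv = np.linalg.inv(BtWB + a * P)
            tr_s = float(np.trace(Ainv @ BtWB))
            gcv = n * dev / max(n - tr_s, 1e-8) ** 2
            if best is None or gcv < best[0]:
                best = (gcv, a, beta, Ainv, BtWB)
        if best is None:
            raise np.linalg.LinAlgError("spline smoother could not be fitted")
        _, self.alpha_, self.beta_, Ainv, BtWB = best
        self._cov = Ainv @ BtWB @ Ainv  # sandwich covariance, link scale
        return self

    @staticmethod
    def _irls(B, P, m, s, alpha, eta0, maxiter=50):
        beta = np.zeros(B.shape[1])
        beta[:] = 0.0
        eta = np.full(m.size, eta0)
        for _ in range(maxiter):
            p = _expit(eta)
            w = m * np.maximum(p * (1 - p), 1e-10)
            z = eta + (s - m * p) / w
            A = B.T @ (B * w[:, None]) + alpha * P
            try:
                new = np.linalg.solve(A, B.T @ (w * z))
            except np.linalg.LinAlgError:
                return beta, False
            eta_new = B @ new
            if np.max(np.abs(new - beta)) < 1e-9:
                return new, True
            beta, eta = new, eta_new
        return beta, True

    def predict_link(self, x_new):
        """Smooth and SE on the linear-predictor (logit) scale."""
        t, deg = self._knots, self.degree
        xc = np.clip(np.asarray(x_new, dtype=float), t[0], t[-1])
        Bg = BSpline.design_matrix(xc, t, deg).toarray()
        fit = Bg @ self.beta_
        var = np.einsum("ij,jk,ik->i", Bg, self._cov, Bg)
        return fit, np.sqrt(np.maximum(var, 0.0))


def _expit(x):
    with np.errstate(over="ignore"):
        return 1.0 / (1.0 + np.exp(-x))


# ---------------------------------------------------------------------------
# sampled GAM ICC check


@dataclass
class GamCheckResult:
    """Smooth-vs-model comparison for every item / cumulative category.

    ``curves`` has one row per (item, k, grid point) with the smooth, the
    sampling-adjusted 95% band and the model ICC; ``coverage`` the fraction
    of grid points per panel where the model curve lies inside the band.
    """

    curves: pd.DataFrame
    coverage: pd.Series  # index (item, k)
    n_samples: int

    def flagged(self, min_coverage: float = 0.9):
        """Panels whose model curve escapes the band too often."""
        return self.coverage[self.coverage < min_coverage]


def sampled_gam_icc_check(
    fit,
    ebe_table: pd.DataFrame,
    dataset: pd.DataFrame,
    n_samples: int = 200,
    seed: int = 0,
    grid_size: int = 100,
    level: float = 0.95,
) -> GamCheckResult:
    """Eta-sampling cross-validated GAM check of the fitted ICCs.

    For every pseudo-individual, ``n_samples`` disability values are drawn
    from N(MAP estimate, SE^2) — the posterior implied by the fitted shift
    parameters and the pseudo-individual's origin — and a GCV cubic-spline
    smooth of each binary indicator (score >= k) against the sampled
    disability is compared with the model's cumulative ICC.  The smooth's
    standard error is multiplied by sqrt(n_samples) so the band has the
    width appropriate to the real number of pseudo-individuals.

    ``fit`` supplies ``item_bank`` (a results object or an ItemBank directly,
    in which case pass the shift via the ebe table's provenance).
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    bank: ItemBank = fit.item_bank if hasattr(fit, "item_bank") else fit
    if "origin" not in dataset.columns:
        dataset = reshape_idvis(dataset)
    if ebe_table["se"].isna().any():
        raise ValueError("every disability estimate needs a standard error")
    rng = np.random.default_rng(seed)
    z = float(norm.ppf(0.5 + level / 2))
    records = []
    coverage = {}
    for dim in bank.dimension_names:
        sub = ebe_table[ebe_table["dim"] == dim]
        merged = dataset.merge(
            sub[["patient_id", "time_months", "ebe", "se"]],
            on=["patient_id", "time_months"],
            how="inner",
        )
        ebe = merged["ebe"].to_numpy()
        se = merged["se"].to_numpy()
        draws = ebe[:, None] + se[:, None] * rng.standard_normal((ebe.size, n_samples))
        x_all = draws.ravel()
        lo, hi = np.quantile(x_all, [0.005, 0.995])
        grid = np.linspace(lo, hi, grid_size)
        items = [it for it in bank.items if it.dimension == dim]
        for it in items:
            scores = merged[f"item{it.index}"].to_numpy(dtype=float)
            obs = ~np.isnan(scores)
            x_obs = draws[obs].ravel()
            for k in range(1, it.max_score + 1):
                y = np.repeat((scores[obs] >= k).astype(float), n_samples)
                sm = _GcvLogisticSpline().fit(x_obs, y)
                eta_g, se_g = sm.predict_link(grid)
                # the sqrt(n_samples) factor widens the band to what the real
                # number of pseudo-individuals supports
                half = z * se_g * np.sqrt(n_samples)
                fit_g = _expit(eta_g)
                lo_g, hi_g = _expit(eta_g - half), _expit(eta_g + half)
                icc = cumulative_probability(it, grid, k)
                inside = (icc >= lo_g) & (icc <= hi_g)
                coverage[(it.index, k)] = float(np.mean(inside))
                records.append(
                    pd.DataFrame(
                        {
                            "item": it.index,
                            "k": k,
                            "psi": grid,
                            "smooth": fit_g,
                            "lo": lo_g,
                            "hi": hi_g,
                            "icc": icc,
                        }
                    )
                )
    curves = pd.concat(records, ignore_index=True)
    cov = pd.Series(coverage).sort_index()
    cov.index.names = ["item", "k"]
    return GamCheckResult(curves=curves, coverage=cov, n_samples=n_samples)


# ---------------------------------------------------------------------------
# residual item correlations


def residual_correlation(fit, ebe_table: pd.DataFrame, dataset: pd.DataFrame):
    """Pearson correlation matrix of item-level residuals.

    The residual of item j for a pseudo-individual is the observed score
    minus the model-expected score at the individual's MAP disability
    (RES = DV - E, with E the probability-weighted mean score).  Under local
    independence the off-diagonal correlations are near zero; structured
    positive blocks signal shared unmodelled dimensions.
    """
    bank: ItemBank = fit.item_bank if hasattr(fit, "item_bank") else fit
    if "origin" not in dataset.columns:
        dataset = reshape_idvis(dataset)
    res = np.full((len(dataset), 7), np.nan)
    for dim in bank.dimension_names:
        sub = ebe_table[ebe_table["dim"] == dim]
        merged = dataset.merge(
            sub[["patient_id", "time_months", "ebe"]],
            on=["patient_id", "time_months"],
            how="left",
        )
        psi = merged["ebe"].to_numpy()
        for j, it in enumerate(bank.items):
            if it.dimension != dim:
                continue
            e = expected_score(it, psi)
            res[:, j] = dataset[ITEM_COLS[j]].to_numpy(dtype=float) - e
    frame = pd.DataFrame(res, columns=ITEM_COLS)
    if (frame.std(skipna=True) < 1e-12).any():
        bad = frame.columns[frame.std(skipna=True) < 1e-12].tolist()
        raise ValueError(f"zero residual variance for {bad}")
    corr = frame.corr()
    corr.index = corr.columns = range(1, 8)
    return corr


# ---------------------------------------------------------------------------
# visual predictive checks


@dataclass
class VpcResult:
    """Observed percentiles vs simulation-based prediction intervals.

    ``table`` has one row per (variable, time bin, percentile) with the
    observed value and the simulation 95% CI; ``n_sim`` the number of
    replicate trials; ``level`` "summary" or "item".
    """

    table: pd.DataFrame
    n_sim: int
    level: str

    def coverage(self, percentile: int = 50) -> float:
        """Fraction of bins whose observed percentile falls inside the CI."""
        sub = self.table[self.table["percentile"] == percentile]
        ok = (sub["observed"] >= sub["sim_lo"]) & (sub["observed"] <= sub["sim_hi"])
        return float(ok.mean())


def _percentiles_by_time(df: pd.DataFrame, col: str, pcts):
    out = {}
    for t, grp in df.groupby("time_months"):
        vals = grp[col].dropna().to_numpy()
        if vals.size:
            out[t] = np.percentile(vals, pcts)
    return out


def vpc(
    simulate_fn,
    dataset: pd.DataFrame,
    n_sim: int | None = None,
    level: str = "summary",
    percentiles=(5, 50, 95),
    seed: int = 0,
) -> VpcResult:
    """Visual predictive check of a simulatable model against a dataset.

    ``simulate_fn(seed)`` must return a replicate dataset at the observed
    design (same schema).  Observed 5th/50th/95th percentiles per nominal
    visit time are compared with the 95% CI of the same percentiles across
    ``n_sim`` replicates (defaults: 200 for summary-score checks, 2000 for
    item-level checks).  ``level="item"`` checks each item's score
    percentiles; ``"summary"`` checks the total score.
    """
    if n_sim is None:
        n_sim = 200 if level == "summary" else 2000
    if n_sim < 20:
        raise ValueError("n_sim must be >= 20 for stable percentile CIs")
    cols = ["total"] if level == "summary" else ITEM_COLS
    obs = {c: _percentiles_by_time(dataset, c, percentiles) for c in cols}
    sims: dict = {c: {} for c in cols}
    for r in range(n_sim):
        rep = simulate_fn(seed + r)
        for c in cols:
            for t, vals in _percentiles_by_time(rep, c, percentiles).items():
                sims[c].setdefault(t, []).append(vals)
    rows = []
    for c in cols:
        for t, o in obs[c].items():
            sim_arr = np.asarray(sims[c].get(t, []))
            if sim_arr.size == 0:
                continue
            lo = np.percentile(sim_arr, 2.5, axis=0)
            hi = np.percentile(sim_arr, 97.5, axis=0)
            med = np.percentile(sim_arr, 50, axis=0)
            for i, p in enumerate(percentiles):
                rows.append(
                    {
                        "variable": c,
                        "time_months": t,
                        "percentile": p,
                        "observed": o[i],
                        "sim_lo": lo[i],
                        "sim_median": med[i],
                        "sim_hi": hi[i],
                    }
                )
    return VpcResult(table=pd.DataFrame(rows), n_sim=n_sim, level=level)
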