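"""Marginal maximum-likelihood estimation of IPSS item characteristic curves.

Estimation follows the IDVIS scheme: every (patient, visit) record is treated
as an independent pseudo-individual.  The latent disability of baseline
pseudo-individuals is fixed to a standard normal distribution, which anchors
the scale; post-baseline pseudo-individuals share an estimated mean/variance
shift (per dimension, with an inter-dimension correlation in the
bidimensional model).  The marginal likelihood integrates the latent
variable(s) with Gauss-Hermite quadrature re-centred on the current prior
(optionally per-individual adaptive quadrature for verification).

The model object is :class:`GradedResponseMML`; its :meth:`fit` returns a
:class:`GradedResponseResults` with estimates, standard errors from the
observed information matrix, OFV (-2 log marginal likelihood), AIC, empirical
Bayes disability estimation and shrinkage summaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.polynomial.hermite import hermgauss
from scipy.optimize import minimize
from scipy.special import logsumexp

from .grm import (
    ItemBank,
    ItemParameters,
    VOIDING_ITEMS,
    category_probabilities,
    increments_from_thresholds,
)

__all__ = [
    "LatentShift",
    "GradedResponseMML",
    "GradedResponseResults",
    "reshape_idvis",
    "reassemble_idvis",
    "fit_icc",
    "estimate_ebe",
    "estimate_disability",
    "shrinkage",
]

ITEM_COLS = [f"item{j}" for j in range(1, 8)]
_MIN_INC = 1e-4


@dataclass(frozen=True)
class LatentShift:
    """Post-baseline latent distribution parameters.

    The baseline latent distribution is fixed to N(0, 1) per dimension (it is
    the scale anchor, not a free parameter).  Post-baseline pseudo-individuals
    are N(post_mean, post_variance) per dimension; in the bidimensional model
    a single correlation is shared by the baseline and post-baseline
    distributions.
    """

    post_mean: tuple
    post_variance: tuple
    correlation: float | None = None

    def __post_init__(self):
        mu = tuple(float(m) for m in np.atleast_1d(self.post_mean))
        var = tuple(float(v) for v in np.atleast_1d(self.post_variance))
        if len(mu) != len(var):
            raise ValueError("post_mean and post_variance must have equal length")
        if any(v <= 0 for v in var):
            raise ValueError("post-baseline variances must be positive")
        if len(mu) == 2 and self.correlation is None:
            raise ValueError("bidimensional shift requires a correlation")
        if self.correlation is not None and not -1 < self.correlation < 1:
            raise ValueError("correlation must lie in (-1, 1)")
        object.__setattr__(self, "post_mean", mu)
        object.__setattr__(self, "post_variance", var)

    @property
    def n_dimensions(self) -> int:
        return len(self.post_mean)

    def prior(self, origin: str):
        """(mean vector, covariance matrix) of the latent prior for an origin."""
        d = self.n_dimensions
        if origin == "baseline":
            mean = np.zeros(d)
            sd = np.ones(d)
        elif origin == "post":
            mean = np.asarray(self.post_mean)
            sd = np.sqrt(self.post_variance)
        else:
            raise ValueError(f"unknown origin {origin!r}")
        cov = np.diag(sd**2)
        if d == 2:
            rho = 0.0 if self.correlation is None else self.correlation
            cov[0, 1] = cov[1, 0] = rho * sd[0] * sd[1]
        return mean, cov


# ---------------------------------------------------------------------------
# IDVIS reshaping


def reshape_idvis(dataset: pd.DataFrame) -> pd.DataFrame:
    """Expand a longitudinal trial dataset into IDVIS pseudo-individuals.

    Each (patient, visit) row becomes an independent pseudo-individual with a
    sequential ``pseudo_id`` and an ``origin`` flag (``"baseline"`` for time
    zero, ``"post"`` otherwise).  The patient/time mapping is retained so the
    longitudinal assignment can be reconciled later.
    """
    required = {"patient_id", "time_months", *ITEM_COLS}
    missing = required - set(dataset.columns)
    if missing:
        raise ValueError(f"dataset lacks columns {sorted(missing)}")
    dup = dataset.duplicated(subset=["patient_id", "time_months"])
    if dup.any():
        rows = dataset.index[dup].tolist()[:5]
        raise ValueError(f"duplicate (patient, visit) rows, e.g. index {rows}")
    out = dataset.copy().reset_index(drop=True)
    out.insert(0, "pseudo_id", np.arange(len(out)))
    out["origin"] = np.where(out["time_months"] == 0, "baseline", "post")
    return out


def reassemble_idvis(pseudo_table: pd.DataFrame) -> pd.DataFrame:
    """Undo :func:`reshape_idvis`, restoring the longitudinal layout."""
    out = pseudo_table.drop(columns=["pseudo_id", "origin"])
    return out.sort_values(["patient_id", "time_months"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# parameter packing

_N_ITEM_PARAMS = 6  # log a, tau1, 4 log-increments


def _pack(bank: ItemBank, shift: LatentShift) -> np.ndarray:
    theta = []
    for it in bank.items:
        inc = increments_from_thresholds(np.asarray(it.thresholds))
        theta.append(np.log(it.discrimination))
        theta.append(inc[0])
        theta.extend(np.log(np.maximum(inc[1:], _MIN_INC)))
    for mu in shift.post_mean:
        theta.append(mu)
    for v in shift.post_variance:
        theta.append(np.log(v))
    if shift.n_dimensions == 2:
        theta.append(np.arctanh(shift.correlation))
    return np.asarray(theta, dtype=float)


def _unpack(theta: np.ndarray, n_dimensions: int):
    items = []
    for j in range(7):
        seg = theta[j * _N_ITEM_PARAMS : (j + 1) * _N_ITEM_PARAMS]
        inc = np.concatenate([[seg[1]], np.exp(seg[2:])])
        tau = np.cumsum(inc)
        dim = (
            "general"
            if n_dimensions == 1
            else ("voiding" if (j + 1) in VOIDING_ITEMS else "storage")
        )
        items.append(
            ItemParameters(
                index=j + 1,
                discrimination=float(np.exp(seg[0])),
                thresholds=tuple(tau),
                dimension=dim,
            )
        )
    bank = ItemBank(items=tuple(items), n_dimensions=n_dimensions)
    k = 7 * _N_ITEM_PARAMS
    if n_dimensions == 1:
        shift = LatentShift(
            post_mean=(theta[k],), post_variance=(float(np.exp(theta[k + 1])),)
        )
    else:
        shift = LatentShift(
            post_mean=(theta[k], theta[k + 1]),
            post_variance=(float(np.exp(theta[k + 2])), float(np.exp(theta[k + 3]))),
            correlation=float(np.tanh(theta[k + 4])),
        )
    return bank, shift


def _param_names(n_dimensions: int):
    names = []
    for j in range(1, 8):
        names.append(f"a{j}")
        names.extend(f"b{j}_{k}" for k in range(1, 6))
    if n_dimensions == 1:
        names += ["post_mean", "post_var"]
    else:
        names += ["post_mean_v", "post_mean_s", "post_var_v", "post_var_s", "corr"]
    return names


def _natural_params(bank: ItemBank, shift: LatentShift) -> np.ndarray:
    """Estimates on the reporting scale (a, first threshold + increments)."""
    vals = []
    for it in bank.items:
        inc = increments_from_thresholds(np.asarray(it.thresholds))
        vals.append(it.discrimination)
        vals.extend(inc)
    vals.extend(shift.post_mean)
    vals.extend(shift.post_variance)
    if shift.n_dimensions == 2:
        vals.append(shift.correlation)
    return np.asarray(vals)


# ---------------------------------------------------------------------------
# model


class GradedResponseMML:
    """Marginal-ML graded response model on IDVIS pseudo-individuals.

    Parameters
    ----------
    pseudo_table : pandas.DataFrame
        Output of :func:`reshape_idvis` (columns ``pseudo_id``, ``origin``,
        ``item1..item7``; scores 0-5 or NaN for missing).
    n_dimensions : int
        1 for the unidimensional model (44 free parameters), 2 for the
        voiding/storage model (47 free parameters).
    n_quad : int
        Gauss-Hermite nodes per dimension (default 21 unidimensional,
        15 bidimensional).
    """

    def __init__(self, pseudo_table: pd.DataFrame, n_dimensions: int = 1, n_quad=None):
        if n_dimensions not in (1, 2):
            raise ValueError("n_dimensions must be 1 or 2")
        self.n_dimensions = n_dimensions
        self.n_quad = int(n_quad) if n_quad else (21 if n_dimensions == 1 else 15)
        if "origin" not in pseudo_table.columns:
            pseudo_table = reshape_idvis(pseudo_table)
        self.pseudo_table = pseudo_table
        y = pseudo_table[ITEM_COLS].to_numpy(dtype=float)
        if np.nanmin(y) < 0 or np.nanmax(y) > 5:
            raise ValueError("item scores must lie in 0..5 (or NaN for missing)")
        self._y = np.where(np.isnan(y), -1, y).astype(np.int64)
        self._is_post = (pseudo_table["origin"] == "post").to_numpy()
        self.n_pseudo_individuals = len(pseudo_table)
        if not self._is_post.any():
            warnings.warn(
                "no post-baseline rows: shift parameters are not identified",
                stacklevel=2,
            )
        z, w = hermgauss(self.n_quad)
        if n_dimensions == 1:
            self._nodes_std = np.sqrt(2.0) * z  # standard-normal nodes
            self._logw = np.log(w) - 0.5 * np.log(np.pi)
        else:
            z1, z2 = np.meshgrid(z, z, indexing="ij")
            self._nodes_std = np.sqrt(2.0) * np.column_stack(
                [z1.ravel(), z2.ravel()]
            )  # (nq^2, 2)
            lw = np.log(w)
            self._logw = (lw[:, None] + lw[None, :]).ravel() - np.log(np.pi)

    @property
    def n_parameters(self) -> int:
        """Free fixed-effect count: 44 unidimensional, 47 bidimensional."""
        return 44 if self.n_dimensions == 1 else 47

    # -- likelihood ---------------------------------------------------------

    def _group_loglik(self, bank: ItemBank, psi_nodes, y_group) -> np.ndarray:
        """Log p(responses | node) summed over items: (n_nodes, n_obs)."""
        n_nodes = psi_nodes.shape[0]
        ll = np.zeros((n_nodes, y_group.shape[0]))
        psi_nodes = np.atleast_2d(psi_nodes.T).T  # (n_nodes, d)
        for j, it in enumerate(bank.items):
            d = bank.dimension_index(it)
            logp = np.log(
                np.maximum(category_probabilities(it, psi_nodes[:, d]), 1e-300)
            )  # (n_nodes, 6)
            yj = y_group[:, j]
            obs = yj >= 0
            if obs.all():
                ll += logp[:, yj]
            else:
                ll[:, obs] += logp[:, yj[obs]]
        return ll

    def _marginal_loglik_rows(self, bank: ItemBank, shift: LatentShift) -> np.ndarray:
        """Per-pseudo-individual log marginal likelihood (prior-centred GH)."""
        out = np.empty(self.n_pseudo_individuals)
        for origin, mask in (("baseline", ~self._is_post), ("post", self._is_post)):
            if not mask.any():
                continue
            mean, cov = shift.prior(origin)
            if self.n_dimensions == 1:
                psi = mean[0] + np.sqrt(cov[0, 0]) * self._nodes_std
            else:
                L = np.linalg.cholesky(cov)
                psi = mean + self._nodes_std @ L.T
            ll = self._group_loglik(bank, psi, self._y[mask])
            out[mask] = logsumexp(ll + self._logw[:, None], axis=0)
        return out

    def loglik(self, bank: ItemBank, shift: LatentShift, quadrature="prior", n_quad=None):
        """Marginal log-likelihood of the full pseudo-individual table.

        ``quadrature="prior"`` (default) centres Gauss-Hermite nodes on the
        origin-specific prior; ``"adaptive"`` re-centres the nodes on each
        pseudo-individual's posterior mode and curvature (slower; used to
        verify quadrature accuracy).  ``n_quad`` overrides the node count.
        """
        if n_quad is not None and n_quad != self.n_quad:
            other = GradedResponseMML(self.pseudo_table, self.n_dimensions, n_quad)
            return other.loglik(bank, shift, quadrature=quadrature)
        if quadrature == "prior":
            return float(self._marginal_loglik_rows(bank, shift).sum())
        if quadrature != "adaptive":
            raise ValueError("quadrature must be 'prior' or 'adaptive'")
        return self._adaptive_loglik(bank, shift)

    def _adaptive_loglik(self, bank: ItemBank, shift: LatentShift) -> float:
        """Per-individual adaptive GH: nodes at posterior mode/curvature."""
        if self.n_dimensions != 1:
            raise NotImplementedError("adaptive quadrature is unidimensional-only")
        total = 0.0
        for origin, mask in (("baseline", ~self._is_post), ("post", self._is_post)):
            if not mask.any():
                continue
            mean, cov = shift.prior(origin)
            sd = float(np.sqrt(cov[0, 0]))
            y = self._y[mask]
            mode, hess = _posterior_mode_1d(bank, y, mean[0], sd)
            shat = 1.0 / np.sqrt(np.maximum(-hess, 1e-12))
            z = self._nodes_std / np.sqrt(2.0)  # raw hermite nodes
            psi = mode[:, None] + shat[:, None] * self._nodes_std[None, :]
            # sum_i w_i exp(z_i^2) g(psi_i) * shat*sqrt2, g = L(psi) * prior pdf
            logprior = -0.5 * np.log(2 * np.pi * sd**2) - 0.5 * (
                (psi - mean[0]) / sd
            ) ** 2
            ll = np.empty_like(psi)
            for i in range(psi.shape[0]):
                ll[i] = self._group_loglik(bank, psi[i], y[i : i + 1])[:, 0]
            logw = np.log(np.exp(self._logw) * np.sqrt(np.pi)) + z**2
            contrib = logsumexp(
                ll + logprior + logw[None, :], axis=1
            ) + np.log(shat * np.sqrt(2.0))
            total += float(contrib.sum())
        return total

    def ofv(self, bank: ItemBank, shift: LatentShift, **kw) -> float:
        """-2 log marginal likelihood."""
        return -2.0 * self.loglik(bank, shift, **kw)

    def _objective(self, theta: np.ndarray) -> float:
        try:
            bank, shift = _unpack(theta, self.n_dimensions)
        except (ValueError, FloatingPointError):
            return 1e12
        val = -2.0 * self._marginal_loglik_rows(bank, shift).sum()
        return val if np.isfinite(val) else 1e12

    # -- starting values ----------------------------------------------------

    def _start(self) -> np.ndarray:
        theta = []
        y = self._y
        for j in range(7):
            yj = y[:, j]
            obs = yj >= 0
            taus = []
            for k in range(1, 6):
                p = np.clip(np.mean(yj[obs] >= k), 1e-3, 1 - 1e-3)
                taus.append(-np.log(p / (1 - p)))
            taus = np.maximum.accumulate(np.asarray(taus))
            inc = np.maximum(increments_from_thresholds(taus), 0.05)
            inc[0] = taus[0]
            theta.append(0.0)  # log a = 0 -> a = 1
            theta.append(inc[0])
            theta.extend(np.log(inc[1:]))
        if self.n_dimensions == 1:
            theta += [-1.0, np.log(1.5)]
        else:
            theta += [-1.0, -1.0, np.log(1.5), np.log(1.5), np.arctanh(0.5)]
        return np.asarray(theta)

    # -- fitting ------------------------------------------------------------

    def fit(
        self,
        start=None,
        n_starts: int = 1,
        seed: int = 0,
        maxiter: int = 500,
        compute_se: bool = True,
    ) -> "GradedResponseResults":
        """Maximise the marginal likelihood.

        ``n_starts > 1`` adds seeded random perturbations of the starting
        vector as extra optimisations; the lowest-OFV solution wins.
        Standard errors come from the numerically differentiated observed
        information matrix, delta-method-mapped to the reporting scale.
        """
        if start is None:
            theta0 = self._start()
        elif isinstance(start, tuple):
            theta0 = _pack(start[0], start[1])
        else:
            theta0 = np.asarray(start, dtype=float)
        rng = np.random.default_rng(seed)
        starts = [theta0]
        for _ in range(n_starts - 1):
            starts.append(theta0 + rng.normal(0.0, 0.2, size=theta0.size))
        best = None
        for th0 in starts:
            res = minimize(
                self._objective,
                th0,
                method="L-BFGS-B",
                options={"maxiter": maxiter, "maxfun": 10 * maxiter * th0.size,
                         "ftol": 1e-10, "gtol": 1e-6},
            )
            if best is None or res.fun < best.fun:
                best = res
        bank, shift = _unpack(best.x, self.n_dimensions)
        ofv = float(best.fun)
        k = best.x.size
        bse = None
        if compute_se:
            bse = self._standard_errors(best.x)
        return GradedResponseResults(
            model=self,
            item_bank=bank,
            latent_shift=shift,
            ofv=ofv,
            k_params=k,
            bse=bse,
            converged=bool(best.success),
            n_pseudo_individuals=self.n_pseudo_individuals,
            theta=best.x.copy(),
        )

    def _standard_errors(self, theta: np.ndarray):
        """Delta-method SEs of natural parameters from the observed information."""
        eps = 1e-4
        n = theta.size
        hess = np.empty((n, n))
        f0 = self._objective(theta)
        # central second differences of OFV
        for i in range(n):
            for j in range(i, n):
                ei = np.zeros(n)
                ej = np.zeros(n)
                ei[i] = eps
                ej[j] = eps
                if i == j:
                    fpp = self._objective(theta + ei)
                    fmm = self._objective(theta - ei)
                    hess[i, i] = (fpp - 2 * f0 + fmm) / eps**2
                else:
                    fpp = self._objective(theta + ei + ej)
                    fpm = self._objective(theta + ei - ej)
                    fmp = self._objective(theta - ei + ej)
                    fmm = self._objective(theta - ei - ej)
                    hess[i, j] = hess[j, i] = (fpp - fpm - fmp + fmm) / (4 * eps**2)
        info = hess / 2.0  # OFV = -2 logL
        try:
            cov_t = np.linalg.inv(info)
        except np.linalg.LinAlgError:
            cov_t = np.linalg.pinv(info)
        # Jacobian of natural params wrt transformed params
        jac = _numeric_jacobian(
            lambda th: _natural_params(*_unpack(th, self.n_dimensions)), theta
        )
        var = np.einsum("ij,jk,ik->i", jac, cov_t, jac)
        return np.sqrt(np.maximum(var, 0.0))


def _numeric_jacobian(fn, x, eps=1e-6):
    f0 = fn(x)
    jac = np.empty((f0.size, x.size))
    for i in range(x.size):
        xp = x.copy()
        xp[i] += eps
        jac[:, i] = (fn(xp) - f0) / eps
    return jac


class GradedResponseResults:
    """Fitted ICC model: item bank, latent shift, fit statistics, EBEs."""

    def __init__(
        self,
        model,
        item_bank,
        latent_shift,
        ofv,
        k_params,
        bse,
        converged,
        n_pseudo_individuals,
        theta,
    ):
        self.model = model
        self.item_bank = item_bank
        self.latent_shift = latent_shift
        self.ofv = ofv
        self.k_params = k_params
        self.bse = bse
        self.converged = converged
        self.n_pseudo_individuals = n_pseudo_individuals
        self._theta = theta
        self.params = pd.Series(
            _natural_params(item_bank, latent_shift),
            index=_param_names(item_bank.n_dimensions),
        )

    @property
    def aic(self) -> float:
        return self.ofv + 2 * self.k_params

    @property
    def se_table(self) -> pd.Series | None:
        if self.bse is None:
            return None
        return pd.Series(self.bse, index=self.params.index)

    def summary(self) -> str:
        dims = self.item_bank.n_dimensions
        lines = [
            f"Graded response model ({'uni' if dims == 1 else 'bi'}dimensional, IDVIS)",
            f"pseudo-individuals: {self.n_pseudo_individuals}   "
            f"parameters: {self.k_params}   converged: {self.converged}",
            f"OFV: {self.ofv:.1f}   AIC: {self.aic:.1f}",
            "",
        ]
        tab = pd.DataFrame({"estimate": self.params})
        if self.bse is not None:
            tab["se"] = self.bse
            with np.errstate(divide="ignore", invalid="ignore"):
                tab["rse%"] = 100 * np.abs(tab["se"] / tab["estimate"])
        lines.append(tab.to_string(float_format=lambda v: f"{v: .4g}"))
        return "\n".join(lines)

    def estimate_disability(self, pseudo_table=None) -> pd.DataFrame:
        """MAP latent disability with SEs for every pseudo-individual."""
        if pseudo_table is None:
            pseudo_table = self.model.pseudo_table
        return estimate_disability(self.item_bank, self.latent_shift, pseudo_table)

    def shrinkage(self, estimates=None) -> dict:
        if estimates is None:
            estimates = self.estimate_disability()
        return shrinkage(self, estimates)


# ---------------------------------------------------------------------------
# empirical Bayes estimation


def _item_derivs_1d(items, y, psi, with_info=False):
    """(loglik, d/dpsi, d2/dpsi2[, Fisher info]) of the response loglik.

    Vectorised over rows; missing scores (-1) contribute nothing.  The
    optional Fisher information is the full-category expected information of
    each observed item, accumulated per row.
    """
    ll = np.zeros_like(psi)
    g = np.zeros_like(psi)
    h = np.zeros_like(psi)
    info = np.zeros_like(psi) if with_info else None
    for j, it in enumerate(items):
        yj = y[:, j]
        obs = yj >= 0
        if not obs.any():
            continue
        a = it.discrimination
        tau = np.asarray(it.thresholds)
        with np.errstate(over="ignore"):
            q = 1.0 / (1.0 + np.exp(-a * (psi[obs, None] - tau)))  # (n, 5)
        qe = np.concatenate(
            [np.ones((q.shape[0], 1)), q, np.zeros((q.shape[0], 1))], axis=1
        )
        w = qe * (1 - qe)
        wp = a * (1 - 2 * qe) * w  # d w / d psi
        yo = yj[obs]
        rows = np.arange(q.shape[0])
        p = np.maximum(qe[rows, yo] - qe[rows, yo + 1], 1e-300)
        u = a * (w[rows, yo] - w[rows, yo + 1])  # dP/dpsi
        up = a * (wp[rows, yo] - wp[rows, yo + 1])  # d2P/dpsi2
        ll[obs] += np.log(p)
        g[obs] += u / p
        h[obs] += up / p - (u / p) ** 2
        if with_info:
            pk = np.maximum(qe[:, :-1] - qe[:, 1:], 1e-300)
            dpk = a * (w[:, :-1] - w[:, 1:])
            info[obs] += np.sum(dpk * dpk / pk, axis=1)
    if with_info:
        return ll, g, h, info
    return ll, g, h


def _posterior_mode_1d(bank, y, prior_mean, prior_sd, tol=1e-9, maxiter=60):
    """Batched Newton ascent of the 1-D posterior; returns (mode, hessian)."""
    n = y.shape[0]
    psi = np.full(n, prior_mean, dtype=float)
    var = prior_sd**2

    def objective(p):
        ll, g, h = _item_derivs_1d(bank.items, y, p)
        post = ll - 0.5 * (p - prior_mean) ** 2 / var
        return post, g - (p - prior_mean) / var, h - 1.0 / var

    f, g, h = objective(psi)
    for _ in range(maxiter):
        step = -g / np.minimum(h, -1e-10)
        step = np.clip(step, -3.0, 3.0)
        new = psi + step
        fn, gn, hn = objective(new)
        worse = fn < f - 1e-12
        shrink = 0
        while worse.any() and shrink < 30:
            step = np.where(worse, step / 2, step)
            new = psi + step
            fn, gn, hn = objective(new)
            worse = fn < f - 1e-12
            shrink += 1
        moved = np.max(np.abs(new - psi))
        psi, f, g, h = new, fn, gn, hn
        if moved < tol:
            break
    bad = ~np.isfinite(psi) | ~np.isfinite(h) | (h >= 0)
    if bad.any():  # grid-search fallback for pathological rows
        grid = np.linspace(-10, 10, 2001)
        for i in np.nonzero(bad)[0]:
            lls = _item_derivs_1d(bank.items, y[i : i + 1].repeat(grid.size, 0), grid)[0]
            post = lls - 0.5 * (grid - prior_mean) ** 2 / var
            psi[i] = grid[np.argmax(post)]
            h[i] = -1.0 / var
    return psi, h


def _posterior_mode_2d(bank, y, mean, cov, tol=1e-9, maxiter=80):
    """Batched 2-D Newton; likelihood Hessian is diagonal per dimension."""
    n = y.shape[0]
    prec = np.linalg.inv(cov)
    psi = np.tile(mean, (n, 1)).astype(float)
    items_by_dim = [
        [(j, it) for j, it in enumerate(bank.items) if bank.dimension_index(it) == d]
        for d in range(2)
    ]

    def objective(p):
        ll = np.zeros(n)
        g = np.zeros((n, 2))
        h_lik = np.zeros((n, 2))
        for d in range(2):
            idx = [j for j, _ in items_by_dim[d]]
            its = [it for _, it in items_by_dim[d]]
            lld, gd, hd = _item_derivs_1d(its, y[:, idx], p[:, d])
            ll += lld
            g[:, d] = gd
            h_lik[:, d] = hd
        dev = p - mean
        ll_post = ll - 0.5 * np.einsum("ni,ij,nj->n", dev, prec, dev)
        g_post = g - dev @ prec
        return ll_post, g_post, h_lik

    f, g, h_lik = objective(psi)
    for _ in range(maxiter):
        H = -np.zeros((n, 2, 2))
        H[:, 0, 0] = h_lik[:, 0]
        H[:, 1, 1] = h_lik[:, 1]
        H -= prec  # full Hessian
        Hneg = -H
        Hneg[:, 0, 0] = np.maximum(Hneg[:, 0, 0], 1e-10)
        Hneg[:, 1, 1] = np.maximum(Hneg[:, 1, 1], 1e-10)
        step = np.linalg.solve(Hneg, g[..., None])[..., 0]
        step = np.clip(step, -3, 3)
        new = psi + step
        fn, gn, hn = objective(new)
        worse = fn < f - 1e-12
        shrink = 0
        while worse.any() and shrink < 30:
            step[worse] /= 2
            new = psi + step
            fn, gn, hn = objective(new)
            worse = fn < f - 1e-12
            shrink += 1
        moved = np.max(np.abs(new - psi))
        psi, f, g, h_lik = new, fn, gn, hn
        if moved < tol:
            break
    H = np.zeros((n, 2, 2))
    H[:, 0, 0] = h_lik[:, 0]
    H[:, 1, 1] = h_lik[:, 1]
    H -= prec
    return psi, H


def estimate_ebe(bank: ItemBank, shift: LatentShift, responses, origin: str):
    """MAP disability estimate with curvature SE for one response vector.

    Returns (ebe, se) arrays of length ``bank.n_dimensions``.  With no
    observed items the posterior equals the prior: ebe = prior mean,
    se = prior SD.
    """
    y = np.asarray(
        [-1 if (r is None or (isinstance(r, float) and np.isnan(r))) else int(r)
         for r in responses],
        dtype=np.int64,
    )[None, :]
    mean, cov = shift.prior(origin)
    if bank.n_dimensions == 1:
        mode, hess = _posterior_mode_1d(bank, y, mean[0], float(np.sqrt(cov[0, 0])))
        se = 1.0 / np.sqrt(-hess)
        return mode, se
    mode, H = _posterior_mode_2d(bank, y, mean, cov)
    covp = np.linalg.inv(-H)
    return mode[0], np.sqrt(np.diagonal(covp, axis1=1, axis2=2))[0]


def estimate_disability(
    bank: ItemBank, shift: LatentShift, pseudo_table: pd.DataFrame
) -> pd.DataFrame:
    """Batched MAP disability estimation for a pseudo-individual table.

    Returns a tidy frame with one row per pseudo-individual and dimension:
    ``patient_id, time_months, origin, dim, ebe, se``.
    """
    if "origin" not in pseudo_table.columns:
        pseudo_table = reshape_idvis(pseudo_table)
    y_all = pseudo_table[ITEM_COLS].to_numpy(dtype=float)
    y_all = np.where(np.isnan(y_all), -1, y_all).astype(np.int64)
    is_post = (pseudo_table["origin"] == "post").to_numpy()
    d = bank.n_dimensions
    ebe = np.empty((len(pseudo_table), d))
    se = np.empty((len(pseudo_table), d))
    for origin, mask in (("baseline", ~is_post), ("post", is_post)):
        if not mask.any():
            continue
        mean, cov = shift.prior(origin)
        if d == 1:
            mode, hess = _posterior_mode_1d(
                bank, y_all[mask], mean[0], float(np.sqrt(cov[0, 0]))
            )
            ebe[mask, 0] = mode
            se[mask, 0] = 1.0 / np.sqrt(-hess)
        else:
            mode, H = _posterior_mode_2d(bank, y_all[mask], mean, cov)
            covp = np.linalg.inv(-H)
            ebe[mask] = mode
            se[mask] = np.sqrt(np.diagonal(covp, axis1=1, axis2=2))
    frames = []
    for k, name in enumerate(bank.dimension_names):
        f = pd.DataFrame(
            {
                "patient_id": pseudo_table["patient_id"].to_numpy(),
                "time_months": pseudo_table["time_months"].to_numpy(),
                "origin": pseudo_table["origin"].to_numpy(),
                "dim": name,
                "ebe": ebe[:, k],
                "se": se[:, k],
            }
        )
        if "pseudo_id" in pseudo_table.columns:
            f.insert(0, "pseudo_id", pseudo_table["pseudo_id"].to_numpy())
        frames.append(f)
    return pd.concat(frames, ignore_index=True)


def shrinkage(fit, estimates: pd.DataFrame) -> dict:
    """SD-based eta-shrinkage of the disability EBEs.

    ``typical`` is ``1 - SD(eta_hat / omega)`` pooled over origins (eta is
    the deviation of the EBE from its origin-specific prior mean, omega the
    prior SD).  Per-pseudo-individual shrinkage uses the conditional-variance
    decomposition ``1 - sqrt(1 - se_i^2 / omega^2)``; its mean, normal 95%
    CI and range are summarised per dimension.
    """
    shift = fit.latent_shift if hasattr(fit, "latent_shift") else fit
    out = {}
    for dim_idx, dim in enumerate(
        ("general",) if shift.n_dimensions == 1 else ("voiding", "storage")
    ):
        sub = estimates[estimates["dim"] == dim]
        if len(sub) < 2:
            raise ValueError("need at least two estimates for shrinkage")
        omega = np.where(
            sub["origin"] == "baseline", 1.0, np.sqrt(shift.post_variance[dim_idx])
        )
        mu = np.where(sub["origin"] == "baseline", 0.0, shift.post_mean[dim_idx])
        eta_std = (sub["ebe"].to_numpy() - mu) / omega
        typical = 1.0 - float(np.std(eta_std, ddof=1))
        ratio = np.clip(1.0 - (sub["se"].to_numpy() / omega) ** 2, 0.0, None)
        indiv = 1.0 - np.sqrt(ratio)
        m = float(np.mean(indiv))
        half = 1.96 * float(np.std(indiv, ddof=1)) / np.sqrt(indiv.size)
        out[dim] = {
            "typical": typical,
            "individual_mean": m,
            "individual_ci": (m - half, m + half),
            "individual_range": (float(np.min(indiv)), float(np.max(indiv))),
        }
    return out


# ---------------------------------------------------------------------------
# functional wrapper


def fit_icc(pseudo_table: pd.DataFrame, n_dimensions: int = 1, **options):
    """Fit the IDVIS graded-response model; see :class:`GradedResponseMML`."""
    n_quad = options.pop("n_quad", None)
    model = GradedResponseMML(pseudo_table, n_dimensions=n_dimensions, n_quad=n_quad)
    return model.fit(**options)
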