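"""Nonlinear mixed-effects models for the time course of IPSS and disability.

Structural model (both the observed total score and the latent disability
scale):

    IPSS or Disability = Baseline + Placebo + Drug
    Placebo = Pmax * (1 - exp(-((ln2 / Tprog) * t)**WEI)) + Drift * t

with Tprog the placebo half-life (months), WEI a Weibull exponent (1 gives
the plain exponential), typical Drift fixed to zero, and Drug an offset
treatment effect applied to active arms after dosing.  Inter-individual
variability may be additive-normal, log-normal or Box-Cox-transformed normal
per parameter.

Three model classes share a batched per-subject Laplace marginalisation:

* :class:`TotalScoreModel` — total IPSS with combined proportional +
  additive residual error;
* :class:`LatentDisabilityModel` — the sequential PSI-IPPSE stage: MAP
  disability estimates modelled with each estimate's standard error entering
  as a known additive residual-variance component;
* :class:`JointIRTModel` — item-level responses with the latent disability
  following the longitudinal model (unidimensional or bidimensional), with
  item characteristic curves fixed or re-estimated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import chi2

from .grm import ItemBank
from .icc import ITEM_COLS, LatentShift, _item_derivs_1d, _pack, _unpack

__all__ = [
    "LongitudinalParams",
    "BidimensionalParams",
    "RandomEffectsSpec",
    "CovariateEffect",
    "boxcox_eta",
    "placebo_response",
    "structural_prediction",
    "TotalScoreModel",
    "LatentDisabilityModel",
    "JointIRTModel",
    "LongitudinalResults",
    "fit_total_score",
    "fit_psi_ippse",
    "fit_joint",
    "covariate_search",
]

LN2 = float(np.log(2.0))


# ---------------------------------------------------------------------------
# parameter containers


@dataclass(frozen=True)
class LongitudinalParams:
    """Typical values of the unidimensional structural model.

    Units are score points for the total-IPSS model and latent-disability
    units for IRT models; ``tprog`` is in months.  ``drift`` is the linear
    slope per month whose typical value is conventionally fixed to zero.
    ``drug`` is the offset treatment effect (negative = improvement).
    """

    baseline: float
    pmax: float
    tprog: float
    wei: float = 1.0
    drift: float = 0.0
    drug: float = 0.0

    def __post_init__(self):
        if self.tprog <= 0:
            raise ValueError("tprog must be positive")
        if self.wei <= 0:
            raise ValueError("wei must be positive")


@dataclass(frozen=True)
class BidimensionalParams:
    """Typical values per latent dimension (voiding, storage).

    ``wei`` is shared between the dimensions, as are the Pmax, Tprog and
    Drift random effects in the associated IIV specification.
    """

    baseline: tuple
    pmax: tuple
    tprog: tuple
    wei: float = 1.0
    drift: tuple = (0.0, 0.0)
    drug: tuple = (0.0, 0.0)

    def __post_init__(self):
        for name in ("baseline", "pmax", "tprog", "drift", "drug"):
            if len(getattr(self, name)) != 2:
                raise ValueError(f"{name} needs one value per dimension")
        if any(t <= 0 for t in self.tprog) or self.wei <= 0:
            raise ValueError("tprog and wei must be positive")


@dataclass(frozen=True)
class RandomEffectsSpec:
    """Distributions, magnitudes and correlations of the random effects.

    ``sd`` holds the standard deviation of the untransformed normal eta for
    each named effect (the conventional percent magnitude is 100 * sd).
    ``distributions`` maps each name to ``"normal"`` (parameter = typical +
    eta) or ``"lognormal"`` (parameter = typical * exp(eta)).
    ``boxcox_shape`` optionally transforms the eta before it is applied:
    eta* = ((exp(eta))**shape - 1) / shape.
    """

    distributions: dict
    sd: dict
    correlations: dict = field(default_factory=dict)
    boxcox_shape: dict = field(default_factory=dict)

    def __post_init__(self):
        for name, dist in self.distributions.items():
            if dist not in ("normal", "lognormal"):
                raise ValueError(f"{name}: unknown distribution {dist!r}")
            if self.sd.get(name, 0.0) < 0:
                raise ValueError(f"{name}: sd must be >= 0")

    @property
    def names(self):
        return tuple(self.distributions)

    def covariance(self) -> np.ndarray:
        names = self.names
        sd = np.array([self.sd[n] for n in names])
        cov = np.diag(sd**2)
        for (n1, n2), rho in self.correlations.items():
            i, j = names.index(n1), names.index(n2)
            cov[i, j] = cov[j, i] = rho * sd[i] * sd[j]
        w = np.linalg.eigvalsh(cov)
        if w.min() < -1e-10:
            raise ValueError("random-effect correlation matrix is not PSD")
        return cov


@dataclass(frozen=True)
class CovariateEffect:
    """A linear covariate effect on a structural parameter.

    ``form="multiplicative"``: Parameter = typical * (1 + coef * (cov - median));
    ``form="additive"``:       Parameter = typical + coef * (cov - median).
    The additive form is meant for parameters whose typical value may be zero
    (e.g. latent baseline disability).
    """

    parameter: str
    covariate: str
    form: str
    coefficient: float
    median: float

    def __post_init__(self):
        if self.form not in ("multiplicative", "additive"):
            raise ValueError("form must be 'multiplicative' or 'additive'")


# ---------------------------------------------------------------------------
# structural functions


def boxcox_eta(eta, shape):
    """Box-Cox transform of a normal random effect: ((e^eta)^shape - 1)/shape.

    Continuous in the shape: the limit shape -> 0 is the identity.
    """
    eta = np.asarray(eta, dtype=float)
    if abs(shape) < 1e-8:
        return eta
    return np.expm1(shape * eta) / shape


def placebo_response(t, pmax, tprog, wei=1.0, drift=0.0):
    """Placebo effect Pmax*(1 - exp(-((ln2/Tprog)*t)**wei)) + drift*t.

    Zero at t = 0; with ``wei = 1`` reaches half of ``pmax`` at ``t = tprog``
    (the half-life definition).
    """
    if tprog <= 0:
        raise ValueError("tprog must be positive")
    t = np.asarray(t, dtype=float)
    u = (LN2 / tprog) * t
    if wei == 1.0:
        s = -np.expm1(-u)
    else:
        s = -np.expm1(-np.power(u, wei, where=u > 0, out=np.zeros_like(u)))
    return pmax * s + drift * t


def structural_prediction(params: LongitudinalParams, arm, t):
    """Typical IPSS or disability at time(s) t for a given arm.

    ``arm`` may be a label (``"placebo"`` is inactive, anything else active),
    a dose in mg (0 = placebo) or a boolean active flag.  The offset drug
    effect applies to active arms at t > 0 only.
    """
    if isinstance(arm, str):
        active = arm.lower() not in ("placebo", "pbo")
    else:
        active = bool(arm)
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("negative times are not allowed")
    pred = params.baseline + placebo_response(
        t, params.pmax, params.tprog, params.wei, params.drift
    )
    if active:
        pred = pred + params.drug * (t > 0)
    return pred


def _apply_covariates(typical: float, name: str, covariates, cov_values) -> np.ndarray:
    """Per-patient typical value after covariate effects (vector over patients)."""
    n = len(next(iter(cov_values.values()))) if cov_values else 1
    out = np.full(n, typical, dtype=float)
    for eff in covariates:
        if eff.parameter != name:
            continue
        c = np.asarray(cov_values[eff.covariate], dtype=float) - eff.median
        if eff.form == "multiplicative":
            out = out * (1.0 + eff.coefficient * c)
        else:
            out = out + eff.coefficient * c
    return out


# ---------------------------------------------------------------------------
# batched Laplace machinery


def _batched_inner_newton(lik, eta0, prec, maxiter=50, tol=1e-9):
    """Minimise m(eta) + eta'P eta per subject; lik returns (m, g, H_GN).

    All quantities are in -2 log-likelihood units.  Returns the per-subject
    mode, the minimised value, and the (GN-approximate) Hessian of the total
    objective at the mode.
    """
    eta = eta0.copy()
    n, K = eta.shape

    def total(e):
        m, g, H = lik(e)
        mt = m + np.einsum("ni,ij,nj->n", e, prec, e)
        gt = g + 2.0 * e @ prec
        Ht = H + 2.0 * prec[None, :, :]
        return mt, gt, Ht

    mt, gt, Ht = total(eta)
    for _ in range(maxiter):
        step = np.linalg.solve(Ht + 1e-10 * np.eye(K)[None], -gt[..., None])[..., 0]
        step = np.nan_to_num(step, nan=0.0, posinf=0.0, neginf=0.0)
        nrm = np.linalg.norm(step, axis=1, keepdims=True)
        step = np.where(nrm > 4.0, step * (4.0 / np.maximum(nrm, 1e-300)), step)
        new = eta + step
        mtn, gtn, Htn = total(new)
        worse = mtn > mt + 1e-10
        halvings = 0
        while worse.any() and halvings < 25:
            step[worse] /= 2.0
            new = eta + step
            mtn, gtn, Htn = total(new)
            worse = mtn > mt + 1e-10
            halvings += 1
        moved = float(np.max(np.abs(new - eta))) if n else 0.0
        eta, mt, gt, Ht = new, mtn, gtn, Htn
        if moved < tol:
            break
    return eta, mt, Ht


def _laplace_ofv(mt, Ht, omega):
    """Per-subject Laplace -2 log marginal likelihood.

    mt is the inner objective at the mode (-2 log p(y|eta) + eta'Om^-1 eta),
    Ht its Hessian (in -2ll units); the Laplace correction is
    log|Omega| + log|Ht/2|.
    """
    K = omega.shape[0]
    sign, logdet_omega = np.linalg.slogdet(omega)
    _, logdet_H = np.linalg.slogdet(Ht)
    return mt + logdet_omega + logdet_H - K * np.log(2.0)


# ---------------------------------------------------------------------------
# shared estimation scaffolding


class _Transform:
    """Named parameter vector with per-entry link functions."""

    def __init__(self, names, links, values):
        self.names = list(names)
        self.links = list(links)
        self.values = np.asarray(values, dtype=float)

    def pack(self, overrides: dict | None = None) -> np.ndarray:
        out = np.empty(len(self.names))
        for i, (name, link, v) in enumerate(zip(self.names, self.links, self.values)):
            if overrides and name in overrides:
                v = overrides[name]
            out[i] = (
                np.log(max(v, 1e-10)) if link == "log"
                else np.arctanh(np.clip(v, -0.999, 0.999)) if link == "atanh"
                else v
            )
        return out

    def unpack(self, theta) -> dict:
        vals = {}
        for name, link, t in zip(self.names, self.links, theta):
            vals[name] = float(np.exp(np.clip(t, -700.0, 50.0))) if link == "log" else (
                float(np.tanh(t)) if link == "atanh" else float(t)
            )
        return vals

    def natural_jacobian(self, theta) -> np.ndarray:
        d = np.empty(len(self.names))
        for i, (link, t) in enumerate(zip(self.links, theta)):
            d[i] = np.exp(t) if link == "log" else (
                1.0 - np.tanh(t) ** 2 if link == "atanh" else 1.0
            )
        return d


class LongitudinalResults:
    """Fitted longitudinal model: estimates, SEs, OFV/AIC, random effects."""

    def __init__(self, model, params_series, bse, ofv, converged, eta_modes, extras=None):
        self.model = model
        self.params = params_series
        self.bse = bse
        self.ofv = float(ofv)
        self.k_params = len(params_series)
        self.converged = bool(converged)
        self.eta_modes = eta_modes
        self.extras = extras or {}

    @property
    def aic(self) -> float:
        return self.ofv + 2 * self.k_params

    @property
    def se_table(self):
        if self.bse is None:
            return None
        return pd.Series(self.bse, index=self.params.index)

    def structural_params(self) -> LongitudinalParams:
        p = self.params
        return LongitudinalParams(
            baseline=p.get("baseline", 0.0),
            pmax=p.get("pmax", 0.0),
            tprog=p.get("tprog", 1.0),
            wei=p.get("wei", 1.0),
            drift=0.0,
            drug=p.get("drug", 0.0),
        )

    def summary(self) -> str:
        lines = [
            f"{type(self.model).__name__}",
            f"subjects: {self.model.n_subjects}   observations: {self.model.n_obs}",
            f"parameters: {self.k_params}   converged: {self.converged}",
            f"OFV: {self.ofv:.2f}   AIC: {self.aic:.2f}",
            "",
        ]
        tab = pd.DataFrame({"estimate": self.params})
        if self.bse is not None:
            tab["se"] = self.bse
            with np.errstate(divide="ignore", invalid="ignore"):
                tab["rse%"] = 100 * np.abs(tab["se"] / tab["estimate"])
        lines.append(tab.to_string(float_format=lambda v: f"{v: .4g}"))
        return "\n".join(lines)


class _LaplaceModelBase:
    """Common outer-optimisation loop for the Laplace-marginalised models."""

    def __init__(self):
        self._eta_cache = None

    # subclasses define: _build_transform(), _objective_parts(values) -> ofv

    def _objective(self, theta) -> float:
        try:
            values = self._transform.unpack(theta)
            val = self._ofv_at(values)
        except (ValueError, np.linalg.LinAlgError, FloatingPointError, OverflowError):
            return 1e12
        return val if np.isfinite(val) else 1e12

    def ofv(self, values: dict | None = None) -> float:
        """OFV at a given parameter dict (default: the starting values)."""
        transform = self._build_transform()
        base = transform.unpack(transform.pack())
        if values:
            base.update(values)
        self._eta_cache = None
        return self._ofv_at(base)

    def fit(
        self,
        maxiter=400,
        compute_se=False,
        ftol=1e-9,
        start_values: dict | None = None,
        n_restarts: int = 3,
        fd_scheme: str = "3-point",
    ) -> LongitudinalResults:
        self._transform = self._build_transform()
        theta0 = self._transform.pack(start_values)
        self._eta_cache = None
        # finite differences with a relative step well above the inner
        # marginalisation noise; restarting from the solution resets the
        # L-BFGS curvature memory and escapes ridge stalls
        opts = {"maxiter": maxiter, "maxfun": 20 * maxiter * max(theta0.size, 1),
                "ftol": ftol, "gtol": 1e-6, "finite_diff_rel_step": 1e-4}
        res = minimize(self._objective, theta0, method="L-BFGS-B",
                       jac=fd_scheme, options=opts)
        for _ in range(max(n_restarts - 1, 0)):
            res2 = minimize(self._objective, res.x, method="L-BFGS-B",
                            jac=fd_scheme, options=opts)
            improved = res.fun - res2.fun
            if res2.fun < res.fun:
                res = res2
            if improved < 0.05:
                break
        values = self._transform.unpack(res.x)
        params = pd.Series({n: values[n] for n in self._transform.names})
        bse = None
        if compute_se:
            bse = self._standard_errors(res.x)
        ofv = self._objective(res.x)
        eta = None if self._eta_cache is None else self._eta_cache.copy()
        return LongitudinalResults(
            model=self,
            params_series=params,
            bse=bse,
            ofv=ofv,
            converged=res.success,
            eta_modes=eta,
        )

    def _standard_errors(self, theta):
        eps = 1e-4
        n = theta.size
        f0 = self._objective(theta)
        hess = np.empty((n, n))
        for i in range(n):
            for j in range(i, n):
                ei = np.zeros(n); ei[i] = eps
                ej = np.zeros(n); ej[j] = eps
                if i == j:
                    hess[i, i] = (
                        self._objective(theta + ei) - 2 * f0 + self._objective(theta - ei)
                    ) / eps**2
                else:
                    hess[i, j] = hess[j, i] = (
                        self._objective(theta + ei + ej)
                        - self._objective(theta + ei - ej)
                        - self._objective(theta - ei + ej)
                        + self._objective(theta - ei - ej)
                    ) / (4 * eps**2)
        try:
            cov = np.linalg.inv(hess / 2.0)
        except np.linalg.LinAlgError:
            cov = np.linalg.pinv(hess / 2.0)
        jac = self._transform.natural_jacobian(theta)
        var = np.maximum(jac**2 * np.diag(cov), 0.0)
        return np.sqrt(var)

    # -- IIV helpers --------------------------------------------------------

    def _omega(self, values) -> np.ndarray:
        names = self.iiv.names
        sd = np.array([values[f"omega_{n}"] for n in names])
        if np.any(sd < 1e-8):
            sd = np.maximum(sd, 1e-8)  # variance near the zero bound
        cov = np.diag(sd**2)
        for (n1, n2), rho0 in self.iiv.correlations.items():
            rho = values.get(f"corr_{n1}_{n2}", rho0 if self.estimate_correlations else rho0)
            if not self.estimate_correlations and not self.use_fixed_correlations:
                rho = 0.0
            i, j = names.index(n1), names.index(n2)
            cov[i, j] = cov[j, i] = rho * sd[i] * sd[j]
        return cov

    def _iiv_param(self, name, typical_vec, eta_col, values):
        """Individual parameter and d(param)/d(eta) for one effect channel."""
        shape = values.get(f"boxcox_{name}", self.iiv.boxcox_shape.get(name))
        if shape is not None:
            eta_star = boxcox_eta(eta_col, shape)
            deta = np.exp(np.clip(shape * eta_col, -60, 60))
        else:
            eta_star = eta_col
            deta = np.ones_like(eta_col)
        if self.iiv.distributions[name] == "lognormal":
            par = typical_vec * np.exp(np.clip(eta_star, -60, 60))
            dpar = par * deta
        else:
            par = typical_vec + eta_star
            dpar = deta
        return par, dpar


def _start_curve_from_means(t, y):
    """(baseline, pmax, tprog) starting values from mean response by time.

    Solves the exponential-progression fraction observed between the first
    post-dose visit and the last visit for the rate constant by bisection;
    falls back to a 3-week half-life when the means are uninformative.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    order = np.argsort(t)
    t, y = t[order], y[order]
    b0 = y[t == 0].mean() if (t == 0).any() else y[0]
    post = t > 0
    if post.sum() < 2:
        return float(b0), -1.0, 0.7
    t1, tT = t[post][0], t[post][-1]
    m1, mT = y[post][0], y[post][-1]
    total_change = mT - b0
    if abs(total_change) < 1e-6:
        return float(b0), -0.5, 0.7
    r = np.clip((m1 - b0) / total_change, 0.05, 0.95)
    lo_k, hi_k = 1e-3, 60.0
    for _ in range(60):
        k = 0.5 * (lo_k + hi_k)
        val = (1 - np.exp(-k * t1)) / (1 - np.exp(-k * tT))
        if val < r:
            lo_k = k
        else:
            hi_k = k
    tprog = float(np.log(2.0) / k)
    pmax = float(total_change / (1 - np.exp(-k * tT)))
    return float(b0), pmax, tprog


def _add_iiv_params(transform_names, links, vals, iiv, estimate_correlations):
    for n in iiv.names:
        transform_names.append(f"omega_{n}")
        links.append("log")
        vals.append(max(iiv.sd[n], 1e-4))
    if estimate_correlations:
        for (n1, n2), rho in iiv.correlations.items():
            transform_names.append(f"corr_{n1}_{n2}")
            links.append("atanh")
            vals.append(rho)


# ---------------------------------------------------------------------------
# structural engine shared by the unidimensional models


class _UniStructuralMixin:
    """Individual predictions and eta-derivatives for the 1-D structural model."""

    def _typicals(self, values):
        cov_vals = self._cov_values
        out = {}
        covs = [
            replace(c, coefficient=values.get(f"cov_{c.parameter}_{c.covariate}", c.coefficient))
            for c in self.covariates
        ]
        for name in ("baseline", "pmax", "tprog", "drift"):
            typ = values.get(name, 0.0)
            out[name] = _apply_covariates(typ, name, covs, cov_vals)
            if len(out[name]) == 1 and self.n_subjects > 1:
                out[name] = np.full(self.n_subjects, out[name][0])
        return out

    def _predict_obs(self, values, eta):
        """f and df/deta at every observation. Returns (f, dfde (N_obs, K))."""
        typ = self._typicals(values)
        names = self.iiv.names
        cols = {n: eta[:, i] for i, n in enumerate(names)}
        zeros = np.zeros(self.n_subjects)
        b, db = self._iiv_param("baseline", typ["baseline"], cols.get("baseline", zeros), values)
        p, dp = self._iiv_param("pmax", typ["pmax"], cols.get("pmax", zeros), values)
        tpr, dtpr = self._iiv_param("tprog", typ["tprog"], cols.get("tprog", zeros), values)
        d, dd = self._iiv_param("drift", typ["drift"], cols.get("drift", zeros), values)
        tpr = np.maximum(tpr, 1e-3)
        wei = values.get("wei", 1.0)
        drug = values.get("drug", 0.0)

        s = self._subj  # observation -> subject
        t = self._t
        u = (LN2 / tpr[s]) * t
        with np.errstate(invalid="ignore"):
            uw = np.power(u, wei, where=u > 0, out=np.zeros_like(u))
        e = np.exp(-uw)
        S = 1.0 - e
        f = b[s] + p[s] * S + d[s] * t + drug * self._active
        dS_dT = np.zeros_like(u)
        pos = u > 0
        dS_dT[pos] = -e[pos] * wei * uw[pos] / tpr[s][pos]
        dfde = np.zeros((self._t.size, len(names)))
        for i, n in enumerate(names):
            if n == "baseline":
                dfde[:, i] = db[s]
            elif n == "pmax":
                dfde[:, i] = S * dp[s]
            elif n == "tprog":
                dfde[:, i] = p[s] * dS_dT * dtpr[s]
            elif n == "drift":
                dfde[:, i] = t * dd[s]
        return f, dfde


# ---------------------------------------------------------------------------
# total-score model


class TotalScoreModel(_LaplaceModelBase, _UniStructuralMixin):
    """Longitudinal model of the total IPSS (0-35) with combined residual error.

    Parameters
    ----------
    data : pandas.DataFrame
        Long-format trial data with columns ``patient_id, time_months,
        dose_mg, total`` and any covariate columns named by ``covariates``.
    iiv : RandomEffectsSpec
        Random-effect specification; also provides starting SDs.
    covariates : list of CovariateEffect
        Covariate structure to estimate (coefficients are free parameters
        started at the provided values).
    include_drug : bool
        Estimate the offset drug effect (False gives the reduced model of
        the drug-effect likelihood-ratio test).
    start : LongitudinalParams, optional
        Starting typical values; derived from the data if omitted.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        iiv: RandomEffectsSpec,
        covariates=(),
        include_drug=True,
        estimate_correlations=False,
        estimate_boxcox=False,
        estimate_wei=False,
        start: LongitudinalParams | None = None,
        residual_start=(0.1, 1.8),
    ):
        super().__init__()
        data = data.dropna(subset=["total"]).reset_index(drop=True)
        self.data = data
        self.iiv = iiv
        self.covariates = list(covariates)
        self.include_drug = include_drug
        self.estimate_correlations = estimate_correlations
        self.use_fixed_correlations = False
        self.estimate_boxcox = estimate_boxcox
        self.estimate_wei = estimate_wei
        self.residual_start = residual_start
        patients = data["patient_id"].drop_duplicates().to_numpy()
        self._patients = patients
        index = {p: i for i, p in enumerate(patients)}
        self.n_subjects = patients.size
        self._subj = data["patient_id"].map(index).to_numpy()
        self._t = data["time_months"].to_numpy(dtype=float)
        dose = data.get("dose_mg", pd.Series(0.0, index=data.index)).to_numpy(dtype=float)
        self._active = ((dose > 0) & (self._t > 0)).astype(float)
        self._y = data["total"].to_numpy(dtype=float)
        self.n_obs = self._y.size
        first = data.groupby("patient_id", sort=False).first()
        self._cov_values = {
            c: first.loc[patients, c].to_numpy(dtype=float)
            for c in {e.covariate for e in self.covariates}
        }
        self._start_params = start or self._default_start()

    def _default_start(self) -> LongitudinalParams:
        placebo = self._active == 0
        # placebo-arm means per visit give the baseline/pmax/tprog shape
        sel = placebo | (self._t == 0)
        means = pd.Series(self._y[sel]).groupby(self._t[sel]).mean()
        b0, p0, tprog = _start_curve_from_means(means.index.to_numpy(),
                                                means.to_numpy())
        return LongitudinalParams(
            baseline=b0, pmax=min(p0, -0.2), tprog=float(np.clip(tprog, 0.05, 12.0)),
            wei=1.0, drift=0.0, drug=-1.0,
        )

    def _build_transform(self) -> _Transform:
        names, links, vals = [], [], []
        sp = self._start_params
        names += ["baseline", "pmax", "tprog"]
        links += ["id", "id", "log"]
        vals += [sp.baseline, sp.pmax, sp.tprog]
        if self.estimate_wei:
            names.append("wei"); links.append("log"); vals.append(sp.wei)
        if self.include_drug:
            names.append("drug"); links.append("id"); vals.append(sp.drug or -1.0)
        for c in self.covariates:
            names.append(f"cov_{c.parameter}_{c.covariate}")
            links.append("id")
            vals.append(c.coefficient)
        _add_iiv_params(names, links, vals, self.iiv, self.estimate_correlations)
        if self.estimate_boxcox:
            for n, shape in self.iiv.boxcox_shape.items():
                names.append(f"boxcox_{n}"); links.append("id"); vals.append(shape)
        names += ["sigma_prop", "sigma_add"]
        links += ["log", "log"]
        vals += list(self.residual_start)
        return _Transform(names, links, vals)

    def _ofv_at(self, values) -> float:
        omega = self._omega(values)
        K = omega.shape[0]
        prec = np.linalg.inv(omega)
        sp2 = values["sigma_prop"] ** 2
        sa2 = values["sigma_add"] ** 2

        def lik(eta):
            f, dfde = self._predict_obs(values, eta)
            v = np.maximum(sp2 * f * f + sa2, 1e-8)
            r = self._y - f
            m_obs = np.log(2 * np.pi * v) + r * r / v
            m = np.bincount(self._subj, weights=m_obs, minlength=self.n_subjects)
            dv_df = 2.0 * sp2 * f
            g_obs = (1.0 / v - r * r / v**2) * dv_df - 2.0 * r / v
            g = np.empty((self.n_subjects, K))
            H = np.empty((self.n_subjects, K, K))
            w_mean = 2.0 / v
            w_var = dv_df * dv_df / v**2
            for i in range(K):
                g[:, i] = np.bincount(
                    self._subj, weights=g_obs * dfde[:, i], minlength=self.n_subjects
                )
                for j in range(i, K):
                    hij = np.bincount(
                        self._subj,
                        weights=(w_mean + w_var) * dfde[:, i] * dfde[:, j],
                        minlength=self.n_subjects,
                    )
                    H[:, i, j] = H[:, j, i] = hij
            return m, g, H

        eta0 = (
            self._eta_cache
            if self._eta_cache is not None and self._eta_cache.shape == (self.n_subjects, K)
            else np.zeros((self.n_subjects, K))
        )
        eta, mt, Ht = _batched_inner_newton(lik, eta0, prec)
        self._eta_cache = eta
        return float(_laplace_ofv(mt, Ht, omega).sum())


# ---------------------------------------------------------------------------
# PSI-IPPSE latent model


class LatentDisabilityModel(_LaplaceModelBase, _UniStructuralMixin):
    """Longitudinal model of MAP disability estimates (PSI-IPPSE stage).

    The dependent variable is the per-visit MAP latent disability; each
    estimate's standard error enters the residual variance as a known,
    observation-specific additive component on top of an estimated additive
    term: Var = se^2 + sigma_add^2.  Baseline-parameter covariate effects
    use the additive form because the typical latent baseline is near zero.

    ``ebe_table`` must carry columns ``patient_id, time_months, ebe, se,
    dose_mg`` (plus covariate columns); rows with missing SEs are rejected —
    the SEs are the point of the method.
    """

    def __init__(
        self,
        ebe_table: pd.DataFrame,
        iiv: RandomEffectsSpec,
        covariates=(),
        include_drug=True,
        estimate_correlations=False,
        start: LongitudinalParams | None = None,
    ):
        super().__init__()
        if "se" not in ebe_table.columns or ebe_table["se"].isna().any():
            raise ValueError("every disability estimate needs a standard error")
        data = ebe_table.reset_index(drop=True)
        self.data = data
        self.iiv = iiv
        self.covariates = list(covariates)
        self.include_drug = include_drug
        self.estimate_correlations = estimate_correlations
        self.use_fixed_correlations = False
        self.estimate_boxcox = False
        patients = data["patient_id"].drop_duplicates().to_numpy()
        self._patients = patients
        index = {p: i for i, p in enumerate(patients)}
        self.n_subjects = patients.size
        self._subj = data["patient_id"].map(index).to_numpy()
        self._t = data["time_months"].to_numpy(dtype=float)
        dose = data.get("dose_mg", pd.Series(0.0, index=data.index)).to_numpy(dtype=float)
        self._active = ((dose > 0) & (self._t > 0)).astype(float)
        self._y = data["ebe"].to_numpy(dtype=float)
        self._se2 = data["se"].to_numpy(dtype=float) ** 2
        self.n_obs = self._y.size
        first = data.groupby("patient_id", sort=False).first()
        self._cov_values = {
            c: first.loc[patients, c].to_numpy(dtype=float)
            for c in {e.covariate for e in self.covariates}
        }
        self._start_params = start or self._default_start()

    def _default_start(self) -> LongitudinalParams:
        placebo = self._active == 0
        sel = placebo | (self._t == 0)
        means = pd.Series(self._y[sel]).groupby(self._t[sel]).mean()
        b0, p0, tprog = _start_curve_from_means(means.index.to_numpy(),
                                                means.to_numpy())
        return LongitudinalParams(
            baseline=b0, pmax=min(p0, -0.1), tprog=float(np.clip(tprog, 0.05, 12.0)),
            wei=1.0, drift=0.0, drug=-0.2,
        )

    def _build_transform(self) -> _Transform:
        names, links, vals = [], [], []
        sp = self._start_params
        names += ["baseline", "pmax", "tprog"]
        links += ["id", "id", "log"]
        vals += [sp.baseline, sp.pmax, sp.tprog]
        if self.include_drug:
            names.append("drug"); links.append("id"); vals.append(sp.drug or -0.2)
        for c in self.covariates:
            names.append(f"cov_{c.parameter}_{c.covariate}")
            links.append("id")
            vals.append(c.coefficient)
        _add_iiv_params(names, links, vals, self.iiv, self.estimate_correlations)
        names.append("sigma_add"); links.append("log"); vals.append(0.3)
        return _Transform(names, links, vals)

    def _ofv_at(self, values) -> float:
        omega = self._omega(values)
        K = omega.shape[0]
        prec = np.linalg.inv(omega)
        v = self._se2 + values["sigma_add"] ** 2

        def lik(eta):
            f, dfde = self._predict_obs(values, eta)
            r = self._y - f
            m_obs = np.log(2 * np.pi * v) + r * r / v
            m = np.bincount(self._subj, weights=m_obs, minlength=self.n_subjects)
            g = np.empty((self.n_subjects, K))
            H = np.empty((self.n_subjects, K, K))
            for i in range(K):
                g[:, i] = np.bincount(
                    self._subj, weights=-2.0 * r / v * dfde[:, i], minlength=self.n_subjects
                )
                for j in range(i, K):
                    hij = np.bincount(
                        self._subj,
                        weights=2.0 / v * dfde[:, i] * dfde[:, j],
                        minlength=self.n_subjects,
                    )
                    H[:, i, j] = H[:, j, i] = hij
            return m, g, H

        eta0 = (
            self._eta_cache
            if self._eta_cache is not None and self._eta_cache.shape == (self.n_subjects, K)
            else np.zeros((self.n_subjects, K))
        )
        eta, mt, Ht = _batched_inner_newton(lik, eta0, prec)
        self._eta_cache = eta
        return float(_laplace_ofv(mt, Ht, omega).sum())


# ---------------------------------------------------------------------------
# joint item-level model


class JointIRTModel(_LaplaceModelBase):
    """Item-level longitudinal IRT model (latent disability + graded ICCs).

    The latent disability of each patient follows the longitudinal structural
    model (per dimension for a bidimensional bank); item responses enter the
    likelihood through the graded-response category probabilities.  The
    per-patient random effects are marginalised with a Laplace approximation.
    With ``re_estimate_icc=False`` (the default, mirroring the sequential
    workflow) the item bank is fixed and only longitudinal parameters move;
    with ``True`` the ICC parameters are appended to the free parameters.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        bank: ItemBank,
        iiv: RandomEffectsSpec,
        covariates=(),
        include_drug=True,
        estimate_correlations=False,
        re_estimate_icc=False,
        start=None,
    ):
        super().__init__()
        self.bank = bank
        self.n_dimensions = bank.n_dimensions
        data = data.reset_index(drop=True)
        self.data = data
        self.iiv = iiv
        self.covariates = list(covariates)
        self.include_drug = include_drug
        self.estimate_correlations = estimate_correlations
        self.use_fixed_correlations = False
        self.estimate_boxcox = False
        self.re_estimate_icc = re_estimate_icc
        patients = data["patient_id"].drop_duplicates().to_numpy()
        self._patients = patients
        index = {p: i for i, p in enumerate(patients)}
        self.n_subjects = patients.size
        self._subj = data["patient_id"].map(index).to_numpy()
        self._t = data["time_months"].to_numpy(dtype=float)
        dose = data.get("dose_mg", pd.Series(0.0, index=data.index)).to_numpy(dtype=float)
        self._active = ((dose > 0) & (self._t > 0)).astype(float)
        y = data[ITEM_COLS].to_numpy(dtype=float)
        self._y = np.where(np.isnan(y), -1, y).astype(np.int64)
        self.n_obs = int((self._y >= 0).sum())
        first = data.groupby("patient_id", sort=False).first()
        self._cov_values = {
            c: first.loc[patients, c].to_numpy(dtype=float)
            for c in {e.covariate for e in self.covariates}
        }
        self._start_params = start
        if self.n_dimensions == 2 and not isinstance(start, BidimensionalParams):
            raise ValueError("bidimensional joint model needs BidimensionalParams start")
        self._items_by_dim = [
            [(j, it) for j, it in enumerate(bank.items) if bank.dimension_index(it) == d]
            for d in range(self.n_dimensions)
        ]

    # -- parameters ---------------------------------------------------------

    def _build_transform(self) -> _Transform:
        names, links, vals = [], [], []
        sp = self._start_params
        if self.n_dimensions == 1:
            sp = sp or LongitudinalParams(0.0, -0.5, 0.7, drug=-0.2)
            names += ["baseline", "pmax", "tprog"]
            links += ["id", "id", "log"]
            vals += [sp.baseline, sp.pmax, sp.tprog]
            if self.include_drug:
                names.append("drug"); links.append("id"); vals.append(sp.drug or -0.2)
        else:
            names += ["baseline_v", "baseline_s", "pmax_v", "pmax_s",
                      "tprog_v", "tprog_s", "wei"]
            links += ["id", "id", "id", "id", "log", "log", "log"]
            vals += [sp.baseline[0], sp.baseline[1], sp.pmax[0], sp.pmax[1],
                     sp.tprog[0], sp.tprog[1], sp.wei]
            if self.include_drug:
                names += ["drug_v", "drug_s"]
                links += ["id", "id"]
                vals += [sp.drug[0] or -0.2, sp.drug[1] or -0.2]
        for c in self.covariates:
            names.append(f"cov_{c.parameter}_{c.covariate}")
            links.append("id")
            vals.append(c.coefficient)
        _add_iiv_params(names, links, vals, self.iiv, self.estimate_correlations)
        if self.re_estimate_icc:
            from .icc import LatentShift as _LS  # packing only needs the bank

            icc_theta = _pack(
                self.bank,
                _LS(
                    post_mean=(0.0,) * self.n_dimensions,
                    post_variance=(1.0,) * self.n_dimensions,
                    correlation=0.5 if self.n_dimensions == 2 else None,
                ),
            )
            n_icc = 7 * 6
            for i in range(n_icc):
                names.append(f"icc_{i}"); links.append("id"); vals.append(icc_theta[i])
        return _Transform(names, links, vals)

    def _current_bank(self, values) -> ItemBank:
        if not self.re_estimate_icc:
            return self.bank
        icc_theta = np.array([values[f"icc_{i}"] for i in range(42)])
        pad = [0.0, 0.0] if self.n_dimensions == 1 else [0.0, 0.0, 0.0, 0.0, 0.3]
        bank, _ = _unpack(np.concatenate([icc_theta, pad]), self.n_dimensions)
        return bank

    # -- latent trajectories -----------------------------------------------

    def _psi_obs(self, values, eta):
        """Latent disability per observation and dimension, with eta-Jacobian."""
        names = self.iiv.names
        cols = {n: eta[:, i] for i, n in enumerate(names)}
        zeros = np.zeros(self.n_subjects)
        s = self._subj
        t = self._t
        psis, jacs = [], []
        covs = [
            replace(c, coefficient=values.get(f"cov_{c.parameter}_{c.covariate}", c.coefficient))
            for c in self.covariates
        ]
        for d in range(self.n_dimensions):
            if self.n_dimensions == 1:
                bname, pname, tname, dname = "baseline", "pmax", "tprog", "drift"
                b_t = values["baseline"]; p_t = values["pmax"]
                t_t = values["tprog"]; wei = values.get("wei", 1.0)
                drug = values.get("drug", 0.0)
            else:
                suffix = "v" if d == 0 else "s"
                bname = f"baseline_{suffix}"
                pname, tname, dname = "pmax", "tprog", "drift"
                b_t = values[f"baseline_{suffix}"]; p_t = values[f"pmax_{suffix}"]
                t_t = values[f"tprog_{suffix}"]; wei = values.get("wei", 1.0)
                drug = values.get(f"drug_{suffix}", 0.0)
            b_typ = _apply_covariates(b_t, bname, covs, self._cov_values)
            if b_typ.size == 1 and self.n_subjects > 1:
                b_typ = np.full(self.n_subjects, b_typ[0])
            b, db = self._iiv_param(bname, b_typ, cols.get(bname, zeros), values) \
                if bname in self.iiv.distributions else (b_typ, zeros)
            p, dp = self._iiv_param(pname, np.full(self.n_subjects, p_t),
                                    cols.get(pname, zeros), values)
            tpr, dtpr = self._iiv_param(tname, np.full(self.n_subjects, t_t),
                                        cols.get(tname, zeros), values)
            dr, ddr = self._iiv_param(dname, zeros, cols.get(dname, zeros), values) \
                if dname in self.iiv.distributions else (zeros, zeros)
            tpr = np.maximum(tpr, 1e-3)
            u = (LN2 / tpr[s]) * t
            with np.errstate(invalid="ignore"):
                uw = np.power(u, wei, where=u > 0, out=np.zeros_like(u))
            e = np.exp(-uw)
            S = 1.0 - e
            psi = b[s] + p[s] * S + dr[s] * t + drug * self._active
            dS_dT = np.zeros_like(u)
            pos = u > 0
            dS_dT[pos] = -e[pos] * wei * uw[pos] / tpr[s][pos]
            jac = np.zeros((t.size, len(names)))
            for i, n in enumerate(names):
                if n == bname:
                    jac[:, i] = db[s]
                elif n == pname:
                    jac[:, i] = S * dp[s]
                elif n == tname:
                    jac[:, i] = p[s] * dS_dT * dtpr[s]
                elif n == dname:
                    jac[:, i] = t * ddr[s]
            psis.append(psi)
            jacs.append(jac)
        return psis, jacs

    def _ofv_at(self, values) -> float:
        omega = self._omega(values)
        K = omega.shape[0]
        prec = np.linalg.inv(omega)
        bank = self._current_bank(values)

        def lik(eta):
            psis, jacs = self._psi_obs(values, eta)
            m = np.zeros(self.n_subjects)
            g = np.zeros((self.n_subjects, K))
            H = np.zeros((self.n_subjects, K, K))
            for d in range(self.n_dimensions):
                idx = [j for j, _ in self._items_by_dim[d]]
                items = [it for _, it in self._items_by_dim[d]]
                ll, gpsi, _, info = _item_derivs_1d(
                    items, self._y[:, idx], psis[d], with_info=True
                )
                m -= 2.0 * np.bincount(self._subj, weights=ll, minlength=self.n_subjects)
                jd = jacs[d]
                for i in range(K):
                    g[:, i] -= 2.0 * np.bincount(
                        self._subj, weights=gpsi * jd[:, i], minlength=self.n_subjects
                    )
                    for j2 in range(i, K):
                        hij = 2.0 * np.bincount(
                            self._subj,
                            weights=info * jd[:, i] * jd[:, j2],
                            minlength=self.n_subjects,
                        )
                        H[:, i, j2] += hij
                        if j2 != i:
                            H[:, j2, i] += hij
            return m, g, H

        eta0 = (
            self._eta_cache
            if self._eta_cache is not None and self._eta_cache.shape == (self.n_subjects, K)
            else np.zeros((self.n_subjects, K))
        )
        eta, mt, Ht = _batched_inner_newton(lik, eta0, prec)
        self._eta_cache = eta
        return float(_laplace_ofv(mt, Ht, omega).sum())


# ---------------------------------------------------------------------------
# functional wrappers and covariate search


def fit_total_score(dataset: pd.DataFrame, iiv=None, **kw) -> LongitudinalResults:
    """Fit the longitudinal total-IPSS model; see :class:`TotalScoreModel`."""
    if iiv is None:
        from .reference import ipss_longitudinal_params

        _, iiv, _ = ipss_longitudinal_params()
    compute_se = kw.pop("compute_se", False)
    maxiter = kw.pop("maxiter", 400)
    return TotalScoreModel(dataset, iiv=iiv, **kw).fit(
        compute_se=compute_se, maxiter=maxiter
    )


def fit_psi_ippse(ebe_table: pd.DataFrame, iiv=None, **kw) -> LongitudinalResults:
    """Fit the PSI-IPPSE latent model; see :class:`LatentDisabilityModel`."""
    if iiv is None:
        from .reference import latent_longitudinal_params

        _, iiv, _ = latent_longitudinal_params()
    compute_se = kw.pop("compute_se", False)
    maxiter = kw.pop("maxiter", 400)
    return LatentDisabilityModel(ebe_table, iiv=iiv, **kw).fit(
        compute_se=compute_se, maxiter=maxiter
    )


def fit_joint(dataset, bank, iiv=None, re_estimate_icc=False, **kw) -> LongitudinalResults:
    """Fit the joint item-level longitudinal model; see :class:`JointIRTModel`."""
    if iiv is None:
        from .reference import latent_longitudinal_params

        _, iiv, _ = latent_longitudinal_params()
    compute_se = kw.pop("compute_se", False)
    maxiter = kw.pop("maxiter", 300)
    return JointIRTModel(
        dataset, bank, iiv=iiv, re_estimate_icc=re_estimate_icc, **kw
    ).fit(compute_se=compute_se, maxiter=maxiter)


def covariate_search(
    fit_fn,
    candidates,
    forward_p: float = 0.01,
    backward_p: float = 0.001,
):
    """Stepwise covariate selection by likelihood-ratio criteria.

    ``fit_fn(covariates)`` must fit the model with the given list of
    :class:`CovariateEffect` and return a results object with ``.ofv``.
    Forward inclusion greedily adds the candidate with the largest
    significant OFV drop (chi-squared, df = 1; threshold 6.635 at p = 0.01),
    then backward elimination removes effects whose removal costs less than
    the stricter threshold (10.828 at p = 0.001).  Returns (final results,
    selected covariates, trace DataFrame).
    """
    fwd_cut = float(chi2.isf(forward_p, 1))
    bwd_cut = float(chi2.isf(backward_p, 1))
    trace = []
    base = fit_fn([])
    selected: list[CovariateEffect] = []
    remaining = list(candidates)
    current = base
    step = 0
    while remaining:
        step += 1
        best = None
        for cand in remaining:
            try:
                res = fit_fn(selected + [cand])
            except (ValueError, np.linalg.LinAlgError):
                warnings.warn(f"candidate {cand.parameter}~{cand.covariate} failed; skipped",
                              stacklevel=2)
                continue
            dofv = current.ofv - res.ofv
            trace.append(
                {"phase": "forward", "step": step,
                 "candidate": f"{cand.parameter}~{cand.covariate}",
                 "dofv": dofv, "decision": ""}
            )
            if dofv > fwd_cut and (best is None or dofv > best[1]):
                best = (cand, dofv, res)
        if best is None:
            break
        cand, dofv, res = best
        for t in trace:
            if t["phase"] == "forward" and t["step"] == step and \
               t["candidate"] == f"{cand.parameter}~{cand.covariate}":
                t["decision"] = "included"
        selected.append(cand)
        remaining.remove(cand)
        current = res
    # backward elimination
    changed = True
    while changed and selected:
        changed = False
        for cand in list(selected):
            others = [c for c in selected if c is not cand]
            res = fit_fn(others)
            dofv = res.ofv - current.ofv
            keep = dofv > bwd_cut
            trace.append(
                {"phase": "backward", "step": step,
                 "candidate": f"{cand.parameter}~{cand.covariate}",
                 "dofv": dofv, "decision": "kept" if keep else "removed"}
            )
            if not keep:
                selected = others
                current = res
                changed = True
                break
    return current, selected, pd.DataFrame(trace)
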