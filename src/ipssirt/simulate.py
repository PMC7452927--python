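"""Synthetic BPH-LUTS trial generation.

Emulates the design of a four-arm, 6-month phase II trial: 403 patients
randomised to placebo or a single 10/20/30 mg dose, visits at 0, 0.5, 1, 2,
3, 4, 5 and 6 months, and a screening requirement of total IPSS >= 13 two
weeks before baseline.  Latent disability trajectories follow the
longitudinal structural model with inter-individual variability; item
responses are drawn from the graded response model by inverting the
cumulative category curves.

Screening is simulated as a separate pre-baseline response vector evaluated
at the patient's baseline latent value plus an independent N(0, 0.3^2) visit
perturbation; rejection sampling enforces the threshold at screening only,
so baseline totals below the cut-off remain possible, as observed in
practice.

Random-number streams are split per patient (stream seeded by
``(seed, patient_index)``), so increasing the sample size never reshuffles
earlier patients.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grm import ItemBank, simulate_item_scores
from .icc import ITEM_COLS, LatentShift
from .longitudinal import (
    BidimensionalParams,
    LongitudinalParams,
    RandomEffectsSpec,
    boxcox_eta,
    placebo_response,
)

__all__ = [
    "TrialDesign",
    "SimulationTruth",
    "default_covariate_distributions",
    "default_truth",
    "generate_population",
    "generate_trajectories",
    "generate_item_responses",
    "simulate_trial",
    "simulate_idvis_dataset",
    "simulate_total_score_trial",
]

SCREENING_PERTURBATION_SD = 0.3  # latent visit-to-visit wiggle at screening


def _cov_factor(cov: np.ndarray) -> np.ndarray:
    """Matrix square root tolerating exactly-zero variances."""
    w, v = np.linalg.eigh(cov)
    return v * np.sqrt(np.clip(w, 0.0, None))

DATA_COLUMNS = [
    "patient_id", "arm", "dose_mg", "time_months", "visit_idx",
    *ITEM_COLS, "total", "qol_base", "bii_base", "region",
]


@dataclass(frozen=True)
class TrialDesign:
    """Design of a synthetic trial.

    ``arms`` is a sequence of (label, dose mg, allocation fraction); the
    fractions must sum to one.  ``visit_times`` are months, strictly
    increasing, starting at the baseline visit (0).  ``screening_threshold``
    applies to the simulated screening total (``None`` disables screening).
    """

    n_patients: int = 403
    arms: tuple = (
        ("placebo", 0.0, 0.25),
        ("10 mg", 10.0, 0.25),
        ("20 mg", 20.0, 0.25),
        ("30 mg", 30.0, 0.25),
    )
    visit_times: tuple = (0.0, 0.5, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0)
    screening_threshold: float | None = 13.0
    item_missingness_rate: float = 0.0
    dropout_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_patients < 1:
            raise ValueError("need at least one patient")
        frac = np.array([a[2] for a in self.arms], dtype=float)
        if abs(frac.sum() - 1.0) > 1e-9 or np.any(frac < 0):
            raise ValueError("arm allocation fractions must be >= 0 and sum to 1")
        vt = np.asarray(self.visit_times, dtype=float)
        if vt[0] != 0 or np.any(np.diff(vt) <= 0):
            raise ValueError("visit_times must start at 0 and strictly increase")
        for r in (self.item_missingness_rate, self.dropout_rate):
            if not 0 <= r <= 1:
                raise ValueError("rates must lie in [0, 1]")


@dataclass(frozen=True)
class SimulationTruth:
    """Ground truth for a synthetic trial.

    Combines the item bank, longitudinal typical values (per dimension for a
    bidimensional bank), the random-effects specification, covariate effects
    and samplers for the baseline covariates they reference.
    """

    item_bank: ItemBank
    longitudinal: object  # LongitudinalParams or BidimensionalParams
    iiv: RandomEffectsSpec
    covariate_effects: tuple = ()
    covariate_distributions: dict = field(default_factory=dict)

    def __post_init__(self):
        needed = {e.covariate for e in self.covariate_effects}
        missing = needed - set(self.covariate_distributions)
        if missing:
            raise ValueError(f"no distribution for covariates {sorted(missing)}")
        bi_bank = self.item_bank.n_dimensions == 2
        bi_par = isinstance(self.longitudinal, BidimensionalParams)
        if bi_bank != bi_par:
            raise ValueError("item bank and longitudinal parameters disagree in dimension")

    @property
    def n_dimensions(self) -> int:
        return self.item_bank.n_dimensions


def default_covariate_distributions() -> dict:
    """Samplers for the baseline covariates of the reference population.

    Quality-of-life score 1-6 (median 4), BPH Impact Index 0-12 (median 7),
    and region coded 0 = North America (about 60%), 1 = Europe.
    """
    return {
        "qol_base": lambda rng: float(
            rng.choice(np.arange(1, 7), p=[0.03, 0.07, 0.20, 0.35, 0.25, 0.10])
        ),
        "bii_base": lambda rng: float(rng.binomial(12, 0.58)),
        "region": lambda rng: float(rng.random() < 0.40),
    }


def default_truth(kind: str = "uni", with_covariates: bool = True) -> SimulationTruth:
    """Reference simulation truth: ``"uni"`` or ``"bi"`` latent model."""
    from . import reference

    if kind == "uni":
        params, iiv, covs = reference.latent_longitudinal_params()
        bank = reference.unidimensional_bank()
    elif kind == "bi":
        params, iiv = reference.bidimensional_longitudinal_params()
        covs = []
        bank = reference.bidimensional_bank()
    else:
        raise ValueError("kind must be 'uni' or 'bi'")
    if not with_covariates:
        covs = []
    return SimulationTruth(
        item_bank=bank,
        longitudinal=params,
        iiv=iiv,
        covariate_effects=tuple(covs),
        covariate_distributions=default_covariate_distributions() if covs else
        default_covariate_distributions(),
    )


# ---------------------------------------------------------------------------
# individual parameters


def _individual_latent_params(truth: SimulationTruth, row) -> dict:
    """Per-dimension structural parameters of one patient from etas/covariates."""
    iiv = truth.iiv
    lp = truth.longitudinal
    out = []
    dims = truth.n_dimensions

    def apply(name, typical):
        eta = row.get(f"eta_{name}", 0.0)
        shape = iiv.boxcox_shape.get(name)
        if shape is not None:
            eta = float(boxcox_eta(eta, shape))
        if name in iiv.distributions and iiv.distributions[name] == "lognormal":
            return typical * np.exp(eta)
        return typical + eta

    for d in range(dims):
        if dims == 1:
            b_t, p_t, t_t, dr_t = lp.baseline, lp.pmax, lp.tprog, lp.drift
            drug = lp.drug
            bname = "baseline"
        else:
            b_t, p_t, t_t, dr_t = lp.baseline[d], lp.pmax[d], lp.tprog[d], lp.drift[d]
            drug = lp.drug[d]
            bname = "baseline_v" if d == 0 else "baseline_s"
        for eff in truth.covariate_effects:
            if eff.parameter == bname:
                c = row[eff.covariate] - eff.median
                if eff.form == "multiplicative":
                    b_t = b_t * (1.0 + eff.coefficient * c)
                else:
                    b_t = b_t + eff.coefficient * c
        out.append(
            {
                "baseline": apply(bname, b_t),
                "pmax": apply("pmax", p_t),
                "tprog": max(apply("tprog", t_t), 1e-3),
                "drift": apply("drift", dr_t),
                "wei": lp.wei,
                "drug": drug,
            }
        )
    return out


def _latent_at(times, pars, active) -> np.ndarray:
    t = np.asarray(times, dtype=float)
    psi = pars["baseline"] + placebo_response(
        t, pars["pmax"], pars["tprog"], pars["wei"], pars["drift"]
    )
    if active:
        psi = psi + pars["drug"] * (t > 0)
    return psi


def _simulate_items_at(bank: ItemBank, psi_by_dim, rng) -> np.ndarray:
    """Scores (n_times, 7) at per-dimension latent vectors."""
    n = np.asarray(psi_by_dim[0]).size
    scores = np.empty((n, bank.n_items), dtype=np.int64)
    for j, it in enumerate(bank.items):
        d = bank.dimension_index(it)
        scores[:, j] = simulate_item_scores(it, np.asarray(psi_by_dim[d], dtype=float), rng)
    return scores


# ---------------------------------------------------------------------------
# population


def generate_population(design: TrialDesign, truth: SimulationTruth) -> pd.DataFrame:
    """Draw patients: arm, baseline covariates and individual random effects.

    When the design has a screening threshold, each patient is re-drawn
    (covariates, etas and screening responses together, within the patient's
    own random stream) until the simulated screening total reaches the
    threshold.
    """
    iiv = truth.iiv
    names = iiv.names
    cov_chol = _cov_factor(iiv.covariance())
    arm_labels = [a[0] for a in design.arms]
    arm_doses = [a[1] for a in design.arms]
    arm_frac = np.array([a[2] for a in design.arms])
    rows = []
    for i in range(design.n_patients):
        rng = np.random.default_rng([design.seed, i])
        arm_idx = int(rng.choice(len(design.arms), p=arm_frac))
        accepted = None
        for _attempt in range(1000):
            covs = {
                name: sampler(rng)
                for name, sampler in truth.covariate_distributions.items()
            }
            etas = cov_chol @ rng.normal(size=len(names))
            row = {f"eta_{n}": e for n, e in zip(names, etas)}
            row.update(covs)
            if design.screening_threshold is None:
                accepted = row
                break
            pars = _individual_latent_params(truth, row)
            psi0 = [p["baseline"] for p in pars]
            psi_scr = [p0 + rng.normal(0.0, SCREENING_PERTURBATION_SD) for p0 in psi0]
            scores = _simulate_items_at(
                truth.item_bank, [np.array([p]) for p in psi_scr], rng
            )
            if scores.sum() >= design.screening_threshold:
                row["screening_total"] = int(scores.sum())
                accepted = row
                break
        if accepted is None:
            raise RuntimeError(
                f"patient {i}: screening rejection did not accept in 1000 attempts"
            )
        accepted.update(
            patient_id=i + 1, arm=arm_labels[arm_idx], dose_mg=arm_doses[arm_idx]
        )
        rows.append(accepted)
    df = pd.DataFrame(rows)
    lead = ["patient_id", "arm", "dose_mg"]
    return df[lead + [c for c in df.columns if c not in lead]]


# ---------------------------------------------------------------------------
# trajectories and responses


def generate_trajectories(
    patients: pd.DataFrame, truth: SimulationTruth, visit_times
) -> pd.DataFrame:
    """Latent disability per patient-visit (one column per dimension).

    At t = 0 the latent value equals the patient's individual baseline
    exactly; the drug offset applies to active arms at post-dose visits.
    """
    vt = np.asarray(visit_times, dtype=float)
    if np.any(vt < 0):
        raise ValueError("negative times are not allowed")
    dims = truth.n_dimensions
    psi_cols = ["psi"] if dims == 1 else ["psi_voiding", "psi_storage"]
    recs = []
    for _, row in patients.iterrows():
        pars = _individual_latent_params(truth, row)
        active = row["dose_mg"] > 0
        psis = [_latent_at(vt, p, active) for p in pars]
        for k, t in enumerate(vt):
            rec = {
                "patient_id": row["patient_id"],
                "arm": row["arm"],
                "dose_mg": row["dose_mg"],
                "time_months": t,
                "visit_idx": k,
            }
            for c, psi in zip(psi_cols, psis):
                rec[c] = psi[k]
            for c in ("qol_base", "bii_base", "region"):
                if c in row:
                    rec[c] = row[c]
            recs.append(rec)
    return pd.DataFrame(recs)


def generate_item_responses(
    trajectories: pd.DataFrame, item_bank: ItemBank, design: TrialDesign
) -> pd.DataFrame:
    """Score the seven items at each patient-visit latent value.

    Dropout removes all visits from the first dropped one on (per-visit
    hazard after baseline); item-level missingness blanks individual scores
    after simulation.  The returned frame follows the long-format trial
    schema with one row per patient-visit.
    """
    psi_cols = ["psi"] if item_bank.n_dimensions == 1 else ["psi_voiding", "psi_storage"]
    for c in psi_cols:
        if c not in trajectories.columns:
            raise ValueError(
                f"trajectory column {c!r} missing: bank has {item_bank.n_dimensions} "
                "dimension(s) but the trajectories were generated differently"
            )
    out_rows = []
    for pid, grp in trajectories.groupby("patient_id", sort=False):
        grp = grp.sort_values("time_months")
        rng = np.random.default_rng([design.seed, int(pid) - 1, 1])
        psi_by_dim = [grp[c].to_numpy() for c in psi_cols]
        scores = _simulate_items_at(item_bank, psi_by_dim, rng).astype(float)
        n_vis = len(grp)
        if design.dropout_rate > 0:
            drop = rng.random(n_vis) < design.dropout_rate
            drop[0] = False
            dropped_from = np.argmax(drop) if drop.any() else n_vis
        else:
            dropped_from = n_vis
        if design.item_missingness_rate > 0:
            miss = rng.random(scores.shape) < design.item_missingness_rate
            scores[miss] = np.nan
        for k, (_, row) in enumerate(grp.iterrows()):
            if k >= dropped_from:
                continue
            rec = {
                "patient_id": row["patient_id"],
                "arm": row["arm"],
                "dose_mg": row["dose_mg"],
                "time_months": row["time_months"],
                "visit_idx": row["visit_idx"],
            }
            for j in range(7):
                rec[ITEM_COLS[j]] = scores[k, j]
            obs = scores[k][~np.isnan(scores[k])]
            rec["total"] = obs.sum() if obs.size == 7 else np.nan
            for c in ("qol_base", "bii_base", "region"):
                rec[c] = row.get(c, np.nan)
            out_rows.append(rec)
    return pd.DataFrame(out_rows, columns=DATA_COLUMNS)


def simulate_trial(design: TrialDesign, truth: SimulationTruth) -> pd.DataFrame:
    """Population -> latent trajectories -> item responses, in one call."""
    patients = generate_population(design, truth)
    traj = generate_trajectories(patients, truth, design.visit_times)
    return generate_item_responses(traj, truth.item_bank, design)


# ---------------------------------------------------------------------------
# IDVIS-style simulation (independent latent value per patient-visit)


def simulate_idvis_dataset(
    bank: ItemBank,
    shift: LatentShift,
    n_patients: int = 403,
    visit_times=(0.0, 0.5, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0),
    seed: int = 0,
    return_psi: bool = False,
) -> pd.DataFrame:
    """Simulate item responses with an independent latent value per visit.

    This reproduces the IDVIS estimation assumptions exactly: baseline
    visits draw psi from N(0, 1) (per dimension, correlated in the
    bidimensional case) and post-baseline visits from the shifted
    distribution.  Used for ICC parameter-recovery studies.
    """
    vt = np.asarray(visit_times, dtype=float)
    d = bank.n_dimensions
    rows = []
    for i in range(n_patients):
        rng = np.random.default_rng([seed, i])
        for k, t in enumerate(vt):
            mean, cov = shift.prior("baseline" if t == 0 else "post")
            psi = mean + np.linalg.cholesky(cov) @ rng.normal(size=d)
            scores = _simulate_items_at(bank, [np.array([p]) for p in psi], rng)[0]
            rec = {
                "patient_id": i + 1,
                "arm": "placebo",
                "dose_mg": 0.0,
                "time_months": t,
                "visit_idx": k,
            }
            rec.update({ITEM_COLS[j]: float(scores[j]) for j in range(7)})
            rec["total"] = float(scores.sum())
            rec.update(qol_base=np.nan, bii_base=np.nan, region=np.nan)
            if return_psi:
                for c, p in zip(
                    ("psi",) if d == 1 else ("psi_voiding", "psi_storage"), psi
                ):
                    rec[c] = p
            rows.append(rec)
    cols = DATA_COLUMNS + (
        [] if not return_psi else (["psi"] if d == 1 else ["psi_voiding", "psi_storage"])
    )
    return pd.DataFrame(rows, columns=cols)


# ---------------------------------------------------------------------------
# total-score simulation


def simulate_total_score_trial(
    design: TrialDesign,
    params: LongitudinalParams,
    iiv: RandomEffectsSpec,
    covariates=(),
    covariate_distributions=None,
    residual=(0.109, 1.892),
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate observed total IPSS directly from the summary-score model.

    Residual error is combined proportional + additive
    (SD = sqrt((prop*f)^2 + add^2)); totals are clipped to the 0-35 scale.
    Screening applies the threshold to a baseline-plus-residual screening
    score.  Item columns are left empty (this path models the composite
    score only).
    """
    if covariate_distributions is None:
        covariate_distributions = default_covariate_distributions() if covariates else {}
    seed = design.seed if seed is None else seed
    sp, sa = residual
    vt = np.asarray(design.visit_times, dtype=float)
    names = iiv.names
    chol = _cov_factor(iiv.covariance())
    arm_frac = np.array([a[2] for a in design.arms])
    rows = []
    for i in range(design.n_patients):
        rng = np.random.default_rng([seed, i])
        arm_idx = int(rng.choice(len(design.arms), p=arm_frac))
        label, dose = design.arms[arm_idx][0], design.arms[arm_idx][1]
        for _attempt in range(1000):
            covs = {n: s(rng) for n, s in covariate_distributions.items()}
            etas = chol @ rng.normal(size=len(names))
            row = {f"eta_{n}": e for n, e in zip(names, etas)}
            row.update(covs)
            truth_like = SimulationTruth(
                item_bank=_dummy_bank(),
                longitudinal=params,
                iiv=iiv,
                covariate_effects=tuple(covariates),
                covariate_distributions=covariate_distributions,
            )
            pars = _individual_latent_params(truth_like, row)[0]
            if design.screening_threshold is not None:
                f0 = pars["baseline"]
                y_scr = f0 + rng.normal(0.0, np.hypot(sp * f0, sa))
                if y_scr < design.screening_threshold:
                    continue
            f = _latent_at(vt, pars, dose > 0)
            y = f + rng.normal(size=vt.size) * np.sqrt((sp * f) ** 2 + sa**2)
            y = np.clip(np.round(y), 0, 35)
            for k, t in enumerate(vt):
                rec = {
                    "patient_id": i + 1, "arm": label, "dose_mg": dose,
                    "time_months": t, "visit_idx": k,
                }
                rec.update({c: np.nan for c in ITEM_COLS})
                rec["total"] = y[k]
                rec["qol_base"] = covs.get("qol_base", np.nan)
                rec["bii_base"] = covs.get("bii_base", np.nan)
                rec["region"] = covs.get("region", np.nan)
                rows.append(rec)
            break
        else:
            raise RuntimeError(f"patient {i}: screening did not accept in 1000 attempts")
    return pd.DataFrame(rows, columns=DATA_COLUMNS)


def _dummy_bank() -> ItemBank:
    from .reference import unidimensional_bank

    return unidimensional_bank()
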