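"""Reference parameter values used as defaults and simulation ground truth.

These are graded-response item banks and longitudinal model estimates
characteristic of a 6-month, four-arm (placebo / 10 / 20 / 30 mg single-dose)
phase II trial in 403 patients with moderate-to-severe BPH-LUTS, with visits
at 0, 0.5, 1, 2, 3, 4, 5 and 6 months and an IPSS >= 13 screening criterion.
They serve as the package's canonical "truth" for synthetic-trial generation
and parameter-recovery testing.

Difficulty values are stored as reported: first threshold followed by strictly
positive increments; absolute thresholds are their cumulative sums
(:func:`ipssirt.grm.thresholds_from_increments`).

The package expresses time in months throughout.  The reference placebo
half-lives (Tprog) are day-scale quantities (12-16 days: the placebo
response is largely developed by the first post-dose month, as the trial's
mean IPSS time course shows) and are converted to months here via
``DAYS_PER_MONTH``.
"""

from __future__ import annotations

import numpy as np

from .grm import ItemBank, ItemParameters, thresholds_from_increments

__all__ = [
    "ITEM_NAMES",
    "unidimensional_bank",
    "bidimensional_bank",
    "unidimensional_shift",
    "bidimensional_shift",
    "ipss_longitudinal_params",
    "latent_longitudinal_params",
    "bidimensional_longitudinal_params",
]

DAYS_PER_MONTH = 30.44

ITEM_NAMES = {
    1: "incomplete emptying",
    2: "frequency",
    3: "intermittency",
    4: "urgency",
    5: "weak stream",
    6: "straining",
    7: "nocturia",
}

# (discrimination, (tau1, increments...)) per item, unidimensional model
_UNI_ITEMS = {
    1: (1.38, (-4.09, 1.82, 1.68, 1.41, 1.27)),
    2: (0.98, (-5.39, 2.64, 2.04, 1.49, 1.55)),
    3: (1.29, (-3.77, 1.80, 1.60, 1.08, 1.34)),
    4: (0.92, (-3.86, 2.09, 1.68, 1.22, 1.42)),
    5: (1.09, (-5.11, 2.31, 1.69, 1.32, 1.12)),
    6: (0.95, (-3.10, 1.72, 1.68, 1.67, 1.67)),
    7: (0.49, (-7.89, 5.19, 3.52, 2.44, 2.10)),
}

# Bidimensional model: items 1,3,5,6 -> voiding; 2,4,7 -> storage
_BI_ITEMS = {
    1: (1.60, (-3.40, 1.56, 1.44, 1.20, 1.09)),
    2: (1.40, (-4.83, 2.24, 1.80, 1.30, 1.30)),
    3: (1.68, (-3.03, 1.48, 1.32, 0.88, 1.10)),
    4: (1.16, (-3.65, 1.88, 1.55, 1.12, 1.27)),
    5: (1.36, (-4.16, 1.90, 1.40, 1.09, 0.93)),
    6: (1.25, (-2.46, 1.38, 1.35, 1.34, 1.34)),
    7: (0.60, (-6.93, 4.40, 3.04, 2.09, 1.77)),
}


def unidimensional_bank() -> ItemBank:
    """Reference unidimensional IPSS item bank (7 items, one latent scale)."""
    items = tuple(
        ItemParameters(
            index=j,
            discrimination=a,
            thresholds=tuple(thresholds_from_increments(raw)),
            dimension="general",
        )
        for j, (a, raw) in sorted(_UNI_ITEMS.items())
    )
    return ItemBank(items=items, n_dimensions=1)


def bidimensional_bank() -> ItemBank:
    """Reference bidimensional bank (voiding: items 1,3,5,6; storage: 2,4,7)."""
    items = tuple(
        ItemParameters(
            index=j,
            discrimination=a,
            thresholds=tuple(thresholds_from_increments(raw)),
            dimension="voiding" if j in (1, 3, 5, 6) else "storage",
        )
        for j, (a, raw) in sorted(_BI_ITEMS.items())
    )
    return ItemBank(items=items, n_dimensions=2)


def unidimensional_shift():
    """Post-baseline latent shift of the unidimensional reference model."""
    from .icc import LatentShift

    return LatentShift(post_mean=(-1.38,), post_variance=(2.22,))


def bidimensional_shift():
    """Post-baseline shift of the bidimensional reference model.

    Dimension order (voiding, storage); the inter-dimension correlation is
    shared by the baseline and post-baseline latent distributions.
    """
    from .icc import LatentShift

    return LatentShift(
        post_mean=(-1.07, -1.40),
        post_variance=(1.61, 2.40),
        correlation=0.691,
    )


def ipss_longitudinal_params():
    """Reference longitudinal total-IPSS model (score units).

    Structural: IPSS = Baseline + Pmax*(1 - exp(-ln2/Tprog * t)) + Drift*t
    + Drug (offset, active arms after dosing).  IIV: log-normal on Baseline
    (Box-Cox shape 1.87) and Tprog, normal on Pmax and Drift (Drift Box-Cox
    shape 39.3); typical Drift fixed to 0.  Residual: combined proportional
    (10.9%) + additive (SD 1.892 score points).  Percent IIV magnitudes are
    100*sqrt(variance) of the untransformed random effect.
    """
    from .longitudinal import CovariateEffect, LongitudinalParams, RandomEffectsSpec

    params = LongitudinalParams(
        baseline=19.6, pmax=-4.12, tprog=15.3 / DAYS_PER_MONTH,
        wei=1.0, drift=0.0, drug=-1.98,
    )
    iiv = RandomEffectsSpec(
        distributions={
            "baseline": "lognormal",
            "pmax": "normal",
            "tprog": "lognormal",
            "drift": "normal",
        },
        sd={"baseline": 0.137, "pmax": 1.217, "tprog": 0.906, "drift": 0.018},
        correlations={("pmax", "drift"): 0.431},
        boxcox_shape={"baseline": 1.87, "drift": 39.3},
    )
    covariates = [
        CovariateEffect("pmax", "qol_base", "multiplicative", 0.208, 4.0),
        CovariateEffect("baseline", "bii_base", "multiplicative", 0.0211, 7.0),
        CovariateEffect("baseline", "qol_base", "multiplicative", 0.0873, 4.0),
        CovariateEffect("baseline", "region", "multiplicative", -0.0803, 0.0),
    ]
    return params, iiv, covariates


def latent_longitudinal_params():
    """Reference longitudinal latent-disability model (unidimensional scale).

    Same structural form as the total-score model but on the latent scale;
    IIV normal on Baseline, Pmax and Drift, log-normal on Tprog.  Baseline
    covariate effects are additive because the typical baseline is near zero.
    """
    from .longitudinal import CovariateEffect, LongitudinalParams, RandomEffectsSpec

    params = LongitudinalParams(
        baseline=0.0283, pmax=-1.03, tprog=12.3 / DAYS_PER_MONTH,
        wei=1.0, drift=0.0, drug=-0.542,
    )
    iiv = RandomEffectsSpec(
        distributions={
            "baseline": "normal",
            "pmax": "normal",
            "tprog": "lognormal",
            "drift": "normal",
        },
        sd={"baseline": 0.759, "pmax": 1.285, "tprog": 0.524, "drift": 0.007},
        correlations={
            ("baseline", "pmax"): 0.017,
            ("baseline", "drift"): 0.092,
            ("pmax", "drift"): 0.34,
        },
    )
    covariates = [
        CovariateEffect("baseline", "bii_base", "additive", 0.121, 7.0),
        CovariateEffect("baseline", "qol_base", "additive", 0.325, 4.0),
        CovariateEffect("baseline", "region", "additive", -0.338, 0.0),
    ]
    return params, iiv, covariates


def bidimensional_longitudinal_params():
    """Reference bidimensional longitudinal latent model (voiding, storage).

    Weibull placebo time course with a common exponent (1.53); separate
    baselines, Pmax, Tprog and drug effects per dimension; the Pmax, Tprog
    and Drift random effects are shared (a single eta applied to both
    dimensions), with correlated baselines.
    """
    from .longitudinal import BidimensionalParams, RandomEffectsSpec

    params = BidimensionalParams(
        baseline=(-0.0251, -0.0667),
        pmax=(-0.75, -0.845),
        tprog=(12.9 / DAYS_PER_MONTH, 13.4 / DAYS_PER_MONTH),
        wei=1.53,
        drift=(0.0, 0.0),
        drug=(-0.488, -0.749),
    )
    iiv = RandomEffectsSpec(
        distributions={
            "baseline_v": "normal",
            "baseline_s": "normal",
            "pmax": "normal",
            "tprog": "lognormal",
            "drift": "normal",
        },
        sd={
            "baseline_v": 0.973,
            "baseline_s": 1.288,
            "pmax": 1.456,
            "tprog": 0.611,
            "drift": 0.006,
        },
        correlations={("baseline_v", "baseline_s"): 0.26, ("pmax", "drift"): 0.40},
    )
    return params, iiv


def arm_table():
    """Default arm labels, doses (mg) and allocation fractions (1:1:1:1)."""
    return [
        ("placebo", 0.0, 0.25),
        ("10 mg", 10.0, 0.25),
        ("20 mg", 20.0, 0.25),
        ("30 mg", 30.0, 0.25),
    ]


def arm_table_exact():
    """Arm allocation preset matching the reference trial's realised counts."""
    n = np.array([98, 101, 99, 105], dtype=float)
    f = n / n.sum()
    return [
        ("placebo", 0.0, f[0]),
        ("10 mg", 10.0, f[1]),
        ("20 mg", 20.0, f[2]),
        ("30 mg", 30.0, f[3]),
    ]
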