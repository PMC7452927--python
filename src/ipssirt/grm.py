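"""Graded response model mathematics for ordered 0-5 questionnaire items.

The International Prostate Symptom Score (IPSS) consists of seven items, each
scored 0-5.  The probability that patient *i* scores at least *k* on item *j*
is modelled with Samejima's graded response model

    P(Y_ij >= k) = logistic(a_j * (psi_i - tau_jk)),   k = 1..5,

where ``a_j`` is the item discrimination (slope), ``tau_jk`` the ordered
category thresholds (difficulty locations) and ``psi_i`` the latent disability
of the patient, oriented so that higher psi means more severe lower urinary
tract symptoms.  Category probabilities follow by differencing adjacent
cumulative curves.  No logistic scaling constant (D = 1.7) is used.

This module provides exact, vectorised kernels used by every estimation and
simulation stage: cumulative and category probabilities, expected item scores,
Fisher item information, response log-likelihoods and categorical simulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import expit

__all__ = [
    "ItemParameters",
    "ItemBank",
    "VOIDING_ITEMS",
    "STORAGE_ITEMS",
    "thresholds_from_increments",
    "increments_from_thresholds",
    "cumulative_probability",
    "category_probabilities",
    "expected_score",
    "item_information",
    "response_loglik",
    "simulate_item_scores",
]

#: IPSS items loading on the voiding dimension (incomplete emptying,
#: intermittency, weak stream, straining) and the storage dimension
#: (frequency, urgency, nocturia) in the bidimensional model.
VOIDING_ITEMS = (1, 3, 5, 6)
STORAGE_ITEMS = (2, 4, 7)

_LOG_FLOOR = 1e-300  # probability floor inside logs; avoids -inf at extreme psi


def thresholds_from_increments(raw):
    """Convert a reported difficulty vector to ordered absolute thresholds.

    Item difficulties are commonly reported as the first threshold followed by
    strictly positive increments between successive thresholds, which
    guarantees the ordering the graded response model requires.  The absolute
    thresholds are the cumulative sums::

        tau_k = raw_1 + sum(raw_2 .. raw_k)

    Parameters
    ----------
    raw : sequence of float
        First threshold followed by positive increments (any length >= 1).

    Returns
    -------
    numpy.ndarray
        Strictly increasing thresholds, same length as ``raw``.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.ndim != 1 or raw.size < 1:
        raise ValueError("raw difficulty vector must be 1-D and non-empty")
    if raw.size > 1 and np.any(raw[1:] <= 0):
        bad = np.nonzero(raw[1:] <= 0)[0] + 2
        raise ValueError(
            f"difficulty increments must be strictly positive; entries {bad.tolist()} "
            "are not (increments are spacings between ordered thresholds)"
        )
    return np.cumsum(raw)


def increments_from_thresholds(tau):
    """Inverse of :func:`thresholds_from_increments`."""
    tau = np.asarray(tau, dtype=float)
    if tau.size > 1 and np.any(np.diff(tau) <= 0):
        raise ValueError("thresholds must be strictly increasing")
    return np.concatenate([tau[:1], np.diff(tau)])


@dataclass(frozen=True)
class ItemParameters:
    """Graded-response parameters of a single ordered item.

    Attributes
    ----------
    index : int
        1-based item number on the questionnaire.
    discrimination : float
        Slope ``a > 0`` on the latent scale of the item's dimension.
    thresholds : tuple of float
        Strictly increasing category thresholds ``tau_1 < ... < tau_m``
        (m = 5 for 0-5 scored items).
    dimension : str
        Latent dimension the item loads on: ``"general"`` for a
        unidimensional model, else ``"voiding"`` or ``"storage"``.
    """

    index: int
    discrimination: float
    thresholds: tuple
    dimension: str = "general"

    def __post_init__(self):
        tau = np.asarray(self.thresholds, dtype=float)
        if tau.size < 1:
            raise ValueError("item needs at least one threshold")
        if tau.size > 1 and np.any(np.diff(tau) <= 0):
            raise ValueError(
                f"item {self.index}: thresholds must be strictly increasing, got {tau}"
            )
        if not self.discrimination > 0:
            raise ValueError(f"item {self.index}: discrimination must be > 0")
        object.__setattr__(self, "thresholds", tuple(float(t) for t in tau))

    @property
    def n_categories(self) -> int:
        """Number of score categories (max score + 1)."""
        return len(self.thresholds) + 1

    @property
    def max_score(self) -> int:
        return len(self.thresholds)


@dataclass(frozen=True)
class ItemBank:
    """The seven IPSS items with their dimension assignment.

    A unidimensional bank maps every item to the single ``general``
    dimension; the bidimensional bank uses the voiding/storage split
    (items 1, 3, 5, 6 voiding; items 2, 4, 7 storage).
    """

    items: tuple
    n_dimensions: int = 1

    def __post_init__(self):
        items = tuple(self.items)
        idx = [it.index for it in items]
        if len(set(idx)) != len(idx):
            raise ValueError("item indices must be unique")
        if self.n_dimensions not in (1, 2):
            raise ValueError("n_dimensions must be 1 or 2")
        if self.n_dimensions == 1:
            if any(it.dimension not in ("general",) for it in items):
                items = tuple(replace(it, dimension="general") for it in items)
        else:
            for it in items:
                want = "voiding" if it.index in VOIDING_ITEMS else "storage"
                if it.dimension != want:
                    raise ValueError(
                        f"bidimensional bank: item {it.index} must load on the "
                        f"{want} dimension (voiding = items {VOIDING_ITEMS}, "
                        f"storage = items {STORAGE_ITEMS})"
                    )
        object.__setattr__(self, "items", items)

    @property
    def n_items(self) -> int:
        return len(self.items)

    @property
    def dimension_names(self):
        return ("general",) if self.n_dimensions == 1 else ("voiding", "storage")

    def dimension_index(self, item: ItemParameters) -> int:
        """Column of the latent vector that this item reads."""
        return self.dimension_names.index(item.dimension)

    @property
    def max_total(self) -> int:
        return sum(it.max_score for it in self.items)

    def to_frame(self):
        """Tidy per-item parameter table (discrimination, thresholds, increments)."""
        import pandas as pd

        rows = []
        for it in self.items:
            tau = np.asarray(it.thresholds)
            inc = increments_from_thresholds(tau)
            row = {"item": it.index, "dimension": it.dimension, "a": it.discrimination}
            row.update({f"tau{k + 1}": tau[k] for k in range(tau.size)})
            row.update({f"inc{k + 1}": inc[k] for k in range(inc.size)})
            rows.append(row)
        return pd.DataFrame(rows).set_index("item")


def cumulative_probability(item: ItemParameters, psi, k: int):
    """P(Y >= k) for category ``k`` of an item at latent value(s) ``psi``.

    ``k`` counts from 1 to the maximum score; the probability is the logistic
    function ``expit(a * (psi - tau_k))`` and is non-increasing in ``k`` and
    non-decreasing in ``psi``.
    """
    if not 1 <= k <= item.max_score:
        raise ValueError(f"category k={k} out of range 1..{item.max_score}")
    psi = np.asarray(psi, dtype=float)
    return expit(item.discrimination * (psi - item.thresholds[k - 1]))


def _cumulative_all(item: ItemParameters, psi):
    """All cumulative curves at once: shape psi.shape + (m,), m = max score."""
    psi = np.asarray(psi, dtype=float)
    tau = np.asarray(item.thresholds)
    return expit(item.discrimination * (psi[..., None] - tau))


def category_probabilities(item: ItemParameters, psi):
    """Probabilities of each score 0..max for an item at latent value(s) psi.

    Returned array has shape ``psi.shape + (max_score + 1,)``; entries are
    non-negative and sum to one (telescoping differences of the cumulative
    curves).
    """
    q = _cumulative_all(item, psi)  # (..., m)
    ones = np.ones_like(q[..., :1])
    zeros = np.zeros_like(ones)
    q_ext = np.concatenate([ones, q, zeros], axis=-1)  # Q_0=1, Q_{m+1}=0
    p = q_ext[..., :-1] - q_ext[..., 1:]
    return np.clip(p, 0.0, 1.0)


def expected_score(item: ItemParameters, psi):
    """Expected item score E[Y | psi] = sum_k k * P(Y = k); in [0, max score]."""
    p = category_probabilities(item, psi)
    k = np.arange(item.n_categories)
    return p @ k


def item_information(item: ItemParameters, psi):
    """Fisher information of one item about the latent disability.

    Computed as the negative expectation of the second derivative of the
    item log-likelihood, which for the graded response model reduces to

        I(psi) = sum_k (dP_k/dpsi)^2 / P_k

    over score categories k = 0..max, with
    ``dP_k/dpsi = a * (Q_k(1-Q_k) - Q_{k+1}(1-Q_{k+1}))`` and ``Q_k`` the
    cumulative curves (Q_0 = 1, Q_{m+1} = 0).  Non-negative everywhere;
    probability floors keep the result finite at extreme psi.
    """
    q = _cumulative_all(item, psi)
    ones = np.ones_like(q[..., :1])
    zeros = np.zeros_like(ones)
    q_ext = np.concatenate([ones, q, zeros], axis=-1)
    w = q_ext * (1.0 - q_ext)  # Q(1-Q), zero at the padded ends
    dp = item.discrimination * (w[..., :-1] - w[..., 1:])
    p = np.maximum(q_ext[..., :-1] - q_ext[..., 1:], _LOG_FLOOR)
    return np.sum(dp * dp / p, axis=-1)


def response_loglik(bank: ItemBank, psi, responses):
    """Log-likelihood of one response vector given per-dimension latent values.

    Parameters
    ----------
    bank : ItemBank
    psi : float or sequence
        Latent value (unidimensional) or per-dimension vector in the order
        of ``bank.dimension_names``.
    responses : sequence
        One score per item in bank order; ``None``/NaN marks a missing item,
        which contributes nothing to the likelihood (missing at random).
    """
    psi_vec = np.atleast_1d(np.asarray(psi, dtype=float))
    if psi_vec.size != bank.n_dimensions:
        if bank.n_dimensions == 1 and psi_vec.size == 1:
            pass
        else:
            raise ValueError(
                f"psi must have {bank.n_dimensions} coordinate(s), got {psi_vec.size}"
            )
    total = 0.0
    for it, y in zip(bank.items, responses):
        if y is None or (isinstance(y, float) and np.isnan(y)):
            continue
        y = int(y)
        if not 0 <= y <= it.max_score:
            raise ValueError(f"item {it.index}: score {y} outside 0..{it.max_score}")
        p = category_probabilities(it, psi_vec[bank.dimension_index(it)])
        total += float(np.log(max(float(p[..., y]), _LOG_FLOOR)))
    return total


def simulate_item_scores(item: ItemParameters, psi, rng):
    """Draw one score per latent value by inverting the cumulative curves.

    The score equals the number of cumulative thresholds exceeded by a single
    uniform draw: ``Y = #{k : U < P(Y >= k)}``, which reproduces the category
    probabilities exactly.
    """
    psi = np.asarray(psi, dtype=float)
    q = _cumulative_all(item, psi)
    u = rng.uniform(size=psi.shape)
    return np.sum(u[..., None] < q, axis=-1).astype(np.int64)
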