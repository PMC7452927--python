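"""Fisher-information curves and information-share ranking of IPSS items.

Each item's Fisher information quantifies its signal-to-noise contribution
to determining a patient's latent disability at a given severity.  Items are
ranked by the area under their information curve over the disability range
of interest (by default the empirical range of the MAP disability
estimates), expressed as a percentage of the total across all seven items.

Information-content assessment is defined for the unidimensional model only:
it gives a single overall perspective across all items, whereas in a
multidimensional model information is only comparable within a dimension.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grm import ItemBank, item_information

__all__ = ["InformationReport", "information_curves", "information_share"]

_DEFAULT_GRID_SIZE = 2001

_SUBSCORE = {1: "voiding", 3: "voiding", 5: "voiding", 6: "voiding",
             2: "storage", 4: "storage", 7: "storage"}


@dataclass(frozen=True)
class InformationReport:
    """Per-item information curves, areas, shares and ranking."""

    grid: np.ndarray
    curves: pd.DataFrame  # one column per item, indexed by grid
    auc: pd.Series
    share: pd.Series  # percent of total
    ranking: tuple  # item indices, most informative first
    range_used: tuple

    def to_frame(self) -> pd.DataFrame:
        """Ranking table: item, subscore category, % of total, cumulative %."""
        rows = []
        cum = 0.0
        for item in self.ranking:
            cum += self.share[item]
            rows.append(
                {
                    "item": item,
                    "subscore": _SUBSCORE[item],
                    "pct_of_total": self.share[item],
                    "cumulative_pct": cum,
                }
            )
        return pd.DataFrame(rows)

    @property
    def voiding_share(self) -> float:
        """Combined share (%) of the voiding items 1, 3, 5 and 6."""
        return float(sum(self.share[j] for j in (1, 3, 5, 6) if j in self.share))


def _require_unidimensional(bank: ItemBank):
    if bank.n_dimensions != 1:
        raise ValueError(
            "information content assessment is restricted to unidimensional "
            "banks: across-dimension information is not comparable in a "
            "multidimensional model"
        )


def information_curves(bank: ItemBank, grid) -> InformationReport:
    """Evaluate each item's Fisher information on a grid of disability values."""
    _require_unidimensional(bank)
    grid = np.asarray(grid, dtype=float)
    curves = pd.DataFrame(
        {it.index: item_information(it, grid) for it in bank.items}, index=grid
    )
    auc = pd.Series(
        {c: float(np.trapezoid(curves[c].to_numpy(), grid)) for c in curves.columns}
    )
    share = 100.0 * auc / auc.sum()
    ranking = tuple(share.sort_values(ascending=False).index)
    return InformationReport(
        grid=grid,
        curves=curves,
        auc=auc,
        share=share,
        ranking=ranking,
        range_used=(float(grid[0]), float(grid[-1])),
    )


def information_share(bank: ItemBank, disability_range, n_grid=_DEFAULT_GRID_SIZE):
    """Rank items by trapezoidal information area over a disability range.

    ``disability_range`` is ``(lo, hi)``; pass the empirical min/max of the
    MAP disability estimates to use "the estimated disability range" of a
    fitted model.  Shares sum to 100%.
    """
    lo, hi = (float(v) for v in disability_range)
    if not lo < hi:
        raise ValueError("disability range must satisfy lo < hi")
    grid = np.linspace(lo, hi, int(n_grid))
    return information_curves(bank, grid)
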