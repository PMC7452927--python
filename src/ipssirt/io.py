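"""Reading, writing and validation of the package's data interchange formats.

A single long-format CSV carries trial data (one row per patient-visit);
YAML carries item banks, fitted models and pipeline configuration.  Output
CSVs start with a comment header recording the package version, a
configuration hash and the seed, so every artifact is traceable.
"""

from __future__ import annotations

import hashlib
import io as _io
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .grm import ItemBank, ItemParameters, increments_from_thresholds
from .icc import ITEM_COLS, LatentShift

__all__ = [
    "read_trial_csv",
    "write_trial_csv",
    "bank_to_dict",
    "bank_from_dict",
    "save_icc_fit",
    "load_icc_fit",
    "load_config",
]

REQUIRED_COLUMNS = ["patient_id", "time_months", *ITEM_COLS]
KNOWN_COLUMNS = [
    "patient_id", "arm", "dose_mg", "time_months", "visit_idx",
    *ITEM_COLS, "total", "qol_base", "bii_base", "region",
]


def read_trial_csv(path) -> pd.DataFrame:
    """Read and validate a long-format trial CSV.

    Checks: required columns present; item scores in 0..5 or blank; times
    non-negative; no duplicate (patient, visit) rows; where a ``total``
    column is present it must equal the item sum on complete rows.
    Validation failures name the offending rows (1-based data rows, header
    excluded).  Row order is preserved.
    """
    df = pd.read_csv(path, comment="#")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    errors = []
    for c in ITEM_COLS:
        vals = df[c]
        bad = vals.notna() & ((vals < 0) | (vals > 5) | (vals % 1 != 0))
        if bad.any():
            rows = (df.index[bad] + 1).tolist()[:5]
            errors.append(f"column {c}: scores outside 0..5 at data row(s) {rows}")
    if (df["time_months"] < 0).any():
        rows = (df.index[df["time_months"] < 0] + 1).tolist()[:5]
        errors.append(f"negative time_months at data row(s) {rows}")
    dup = df.duplicated(subset=["patient_id", "time_months"])
    if dup.any():
        rows = (df.index[dup] + 1).tolist()[:5]
        errors.append(f"duplicate (patient, visit) at data row(s) {rows}")
    if "total" in df.columns:
        items = df[ITEM_COLS]
        complete = items.notna().all(axis=1) & df["total"].notna()
        mism = complete & (items.sum(axis=1) != df["total"])
        if mism.any():
            rows = (df.index[mism] + 1).tolist()[:5]
            errors.append(f"total differs from the item sum at data row(s) {rows}")
    if errors:
        raise ValueError(f"{path}: validation failed:\n  " + "\n  ".join(errors))
    return df


def write_trial_csv(df: pd.DataFrame, path, seed=None, config=None):
    """Write a trial CSV with a provenance comment header."""
    from . import __version__

    cfg_hash = "-"
    if config is not None:
        blob = yaml.safe_dump(config, sort_keys=True).encode()
        cfg_hash = hashlib.sha256(blob).hexdigest()[:12]
    header = f"# ipssirt {__version__}  config={cfg_hash}  seed={seed}\n"
    buf = _io.StringIO()
    df.to_csv(buf, index=False)
    Path(path).write_text(header + buf.getvalue())


# ---------------------------------------------------------------------------
# item banks and fits


def bank_to_dict(bank: ItemBank) -> dict:
    return {
        "n_dimensions": bank.n_dimensions,
        "items": [
            {
                "item": it.index,
                "dimension": it.dimension,
                "a": float(it.discrimination),
                "thresholds": [float(t) for t in it.thresholds],
                "increments": [float(v) for v in increments_from_thresholds(
                    np.asarray(it.thresholds))],
            }
            for it in bank.items
        ],
    }


def bank_from_dict(d: dict) -> ItemBank:
    items = tuple(
        ItemParameters(
            index=int(e["item"]),
            discrimination=float(e["a"]),
            thresholds=tuple(e["thresholds"]),
            dimension=e.get("dimension", "general"),
        )
        for e in d["items"]
    )
    return ItemBank(items=items, n_dimensions=int(d.get("n_dimensions", 1)))


def save_icc_fit(results, path):
    """Serialise a fitted (or reference) ICC model to YAML."""
    shift: LatentShift = results.latent_shift
    payload = {
        "bank": bank_to_dict(results.item_bank),
        "shift": {
            "post_mean": list(shift.post_mean),
            "post_variance": list(shift.post_variance),
            "correlation": shift.correlation,
        },
        "ofv": getattr(results, "ofv", None),
        "aic": getattr(results, "aic", None),
        "converged": getattr(results, "converged", None),
        "n_pseudo_individuals": getattr(results, "n_pseudo_individuals", None),
    }
    se = getattr(results, "se_table", None)
    if se is not None:
        payload["se"] = {str(k): float(v) for k, v in se.items()}
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def load_icc_fit(path):
    """Load an ICC fit YAML; returns (ItemBank, LatentShift, metadata dict)."""
    d = yaml.safe_load(Path(path).read_text())
    bank = bank_from_dict(d["bank"])
    s = d["shift"]
    shift = LatentShift(
        post_mean=tuple(s["post_mean"]),
        post_variance=tuple(s["post_variance"]),
        correlation=s.get("correlation"),
    )
    meta = {k: d.get(k) for k in ("ofv", "aic", "converged", "n_pseudo_individuals", "se")}
    return bank, shift, meta


def load_config(path) -> dict:
    """Load a pipeline/simulation YAML configuration."""
    cfg = yaml.safe_load(Path(path).read_text())
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: configuration must be a mapping")
    return cfg
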