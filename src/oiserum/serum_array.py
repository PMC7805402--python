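"""Antibody-array spot processing and fold-change profiling.

Per array: duplicate spots are averaged per protein, the background (mean of
blank and negative-control spots) is subtracted, and intensities are scaled
so the positive controls map to 1 — making profiles invariant to a global
scanner gain. Fold changes of each post-infusion array versus the basal
array flag upregulated proteins (strictly above the fold-change threshold),
and the commonly upregulated set is the intersection across tables.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import SpotTable

__all__ = [
    "ArrayConfig",
    "average_duplicates",
    "normalize_controls",
    "normalize_array",
    "fold_change_vs_basal",
    "common_upregulated",
]


@dataclass
class ArrayConfig:
    """fc_threshold: upregulation calls use fold_change > fc_threshold
    (strict). floor: pseudo-intensity added to numerator and denominator
    before ratios; None means automatic — zero when every basal intensity is
    positive (so clean data recovers planted fold changes exactly), otherwise
    the smallest positive normalized intensity."""

    fc_threshold: float = 1.3
    floor: float | None = None

    def __post_init__(self) -> None:
        if not self.fc_threshold > 1:
            raise ValueError("fc_threshold must be > 1")
        if self.floor is not None and self.floor < 0:
            raise ValueError("floor must be >= 0")


def average_duplicates(t: SpotTable) -> pd.Series:
    """Arithmetic mean of the two spots per protein (NaN when a spot is missing)."""
    spots = t.spots[["spot1", "spot2"]].astype(float)
    out = spots.mean(axis=1, skipna=False)
    out.name = t.array_id
    return out


def normalize_controls(intensities: pd.Series, t: SpotTable) -> pd.Series:
    """Normalize against blank, negative and positive control spots.

    Background = mean of blank and negative control spots is subtracted
    (clipped at 0); the result is divided by (mean positive control -
    background), anchoring each array's positive controls at 1.
    """
    background = float(np.concatenate([t.controls["blank"], t.controls["negative"]]).mean())
    scale = float(np.mean(t.controls["positive"])) - background
    if scale <= 0:
        raise ValueError(
            f"array {t.array_id!r}: positive-control mean does not exceed background"
        )
    out = ((intensities - background).clip(lower=0)) / scale
    out.name = t.array_id
    return out


def normalize_array(t: SpotTable) -> pd.Series:
    """Duplicate averaging followed by control normalization, one array."""
    return normalize_controls(average_duplicates(t), t)


def fold_change_vs_basal(
    profiles: pd.DataFrame,
    basal_id: str,
    cfg: ArrayConfig | None = None,
) -> pd.DataFrame:
    """Fold changes of every non-basal array versus the basal array.

    ``profiles`` holds normalized intensities (proteins x arrays). The result
    has a two-level column index (array, {intensity, fold_change,
    upregulated}); proteins with a missing intensity in an array are excluded
    from that array's calls (NaN fold change, not upregulated).
    """
    cfg = cfg or ArrayConfig()
    if basal_id not in profiles.columns:
        raise KeyError(f"unknown basal array {basal_id!r}")
    basal = profiles[basal_id].astype(float)
    floor = cfg.floor
    if floor is None:
        positive = profiles.to_numpy(dtype=float)
        positive = positive[np.isfinite(positive) & (positive > 0)]
        floor = 0.0 if (basal.dropna() > 0).all() and len(basal.dropna()) else (
            float(positive.min()) if positive.size else 1.0
        )
    blocks = {}
    for col in profiles.columns:
        if col == basal_id:
            continue
        x = profiles[col].astype(float)
        fc = (x + floor) / (basal + floor)
        blocks[col] = pd.DataFrame(
            {
                "intensity": x,
                "fold_change": fc,
                "upregulated": (fc > cfg.fc_threshold).fillna(False),
            }
        )
    if not blocks:
        raise ValueError("profiles contain no non-basal arrays")
    return pd.concat(blocks, axis=1)


def upregulated_set(fc_table: pd.DataFrame, array_id: str) -> set[str]:
    """Proteins flagged upregulated in one array of a fold-change table."""
    flags = fc_table[(array_id, "upregulated")]
    return set(flags.index[flags.astype(bool)])


def common_upregulated(tables) -> set[str]:
    """Intersection of upregulated protein sets across fold-change calls.

    ``tables`` is an iterable whose elements are either sets of protein ids
    or single-array fold-change frames with an ``upregulated`` column.
    """
    sets = []
    for t in tables:
        if isinstance(t, set):
            sets.append(t)
        elif isinstance(t, pd.DataFrame):
            if isinstance(t.columns, pd.MultiIndex):
                for arr in t.columns.get_level_values(0).unique():
                    sets.append(upregulated_set(t, arr))
            else:
                flags = t["upregulated"].astype(bool)
                sets.append(set(t.index[flags]))
        else:
            sets.append(set(t))
    if len(sets) < 2:
        raise ValueError("need at least two upregulated sets to intersect")
    return set.intersection(*sets)
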