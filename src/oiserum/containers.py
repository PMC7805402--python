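"""Typed data containers shared across pipeline stages.

The pipeline's lingua franca is the pandas DataFrame; these thin dataclasses
bundle a frame with the metadata the downstream operations need (pairing maps,
pixel sizes, control spots) and validate the structural invariants once, at
construction time, so every stage can assume them.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CONDITIONS = ("basal", "post")
BIOMARKER_FEATURES = ("bvtv", "tbth", "tbsp", "tbn")


def _validate_pairing(values: pd.DataFrame, pairing: pd.DataFrame) -> pd.DataFrame:
    if not {"line_id", "condition"}.issubset(pairing.columns):
        raise ValueError("pairing table needs 'line_id' and 'condition' columns")
    pairing = pairing.copy()
    pairing.index = pairing.index.astype(str)
    samples = set(map(str, values.columns))
    paired = set(pairing.index)
    missing = sorted(samples - paired)
    if missing:
        raise ValueError(f"samples missing from pairing table: {missing}")
    extra = sorted(paired - samples)
    if extra:
        raise ValueError(f"pairing table lists unknown samples: {extra}")
    bad = sorted(set(pairing["condition"]) - set(CONDITIONS))
    if bad:
        raise ValueError(f"conditions must be one of {CONDITIONS}, got {bad}")
    for line_id, grp in pairing.groupby("line_id"):
        counts = grp["condition"].value_counts()
        if counts.get("basal", 0) != 1 or counts.get("post", 0) != 1:
            raise ValueError(
                f"line {line_id!r} must have exactly one basal and one post sample"
            )
    return pairing


@dataclass
class ExpressionMatrix:
    """Gene-level expression, genes x samples, with a paired-design map.

    Parameters
    ----------
    values
        Non-negative expression values (counts or FPKM or a transform
        thereof), genes in rows, samples in columns. Gene ids must be unique.
    pairing
        Optional table indexed by sample id with columns ``line_id`` and
        ``condition`` in ``{"basal", "post"}``; each line must contribute
        exactly one sample per condition. Required by the vote selector.
    """

    values: pd.DataFrame
    pairing: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.values.size == 0:
            raise ValueError("empty expression matrix")
        dup = self.values.index[self.values.index.duplicated()].unique().tolist()
        if dup:
            raise ValueError(f"duplicate gene ids: {dup}")
        arr = self.values.to_numpy(dtype=float)
        if np.isnan(arr).any():
            raise ValueError("expression matrix contains NaN")
        if (arr < 0).any():
            raise ValueError("expression values must be non-negative")
        self.values = self.values.astype(float)
        self.values.columns = self.values.columns.astype(str)
        if self.pairing is not None:
            self.pairing = _validate_pairing(self.values, self.pairing)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_lines(self) -> int:
        if self.pairing is None:
            raise ValueError("matrix has no pairing information")
        return self.pairing["line_id"].nunique()

    def line_pairs(self) -> tuple[list, list[str], list[str]]:
        """Return (line_ids, basal_sample_ids, post_sample_ids), line-aligned."""
        if self.pairing is None:
            raise ValueError("matrix has no pairing information")
        lines, basal, post = [], [], []
        for line_id, grp in sorted(self.pairing.groupby("line_id"), key=lambda kv: str(kv[0])):
            lines.append(line_id)
            basal.append(grp.index[grp["condition"] == "basal"][0])
            post.append(grp.index[grp["condition"] == "post"][0])
        return lines, basal, post

    def with_values(self, values: pd.DataFrame) -> "ExpressionMatrix":
        return ExpressionMatrix(values=values, pairing=None if self.pairing is None else self.pairing.copy())


@dataclass
class RadiographROI:
    """A grayscale radiograph region of interest with physical pixel size."""

    pixels: np.ndarray
    pixel_size: float = 1.0  # mm / pixel
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("ROI pixels must be a 2-D array")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be > 0")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.pixels.shape:
                raise ValueError("mask shape must match pixel shape")

    def effective_mask(self) -> np.ndarray:
        if self.mask is None:
            return np.ones(self.pixels.shape, dtype=bool)
        return self.mask


@dataclass
class BinarizedROI:
    """Otsu-binarized ROI: trabecular bone foreground vs marrow background."""

    foreground: np.ndarray
    mask: np.ndarray
    threshold: float

    def __post_init__(self) -> None:
        self.foreground = np.asarray(self.foreground, dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.foreground.shape != self.mask.shape:
            raise ValueError("foreground and mask shapes differ")
        if (self.foreground & ~self.mask).any():
            raise ValueError("foreground must lie within the mask")

    @property
    def background(self) -> np.ndarray:
        return self.mask & ~self.foreground


@dataclass
class MicrostructureBiomarkers:
    """The five 2-D trabecular biomarkers of one ROI.

    bvtv is stored as a fraction in [0, 1] (render as % in reports);
    tbth and tbsp are in mm; tbn = bvtv / tbth in 1/mm; qts is the optional
    PCA-composite score (reference-population dependent).
    """

    bvtv: float
    tbth: float
    tbsp: float
    tbn: float
    qts: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.bvtv <= 1.0:
            raise ValueError("bvtv must be a fraction in [0, 1]")

    def as_series(self) -> pd.Series:
        d = {k: getattr(self, k) for k in BIOMARKER_FEATURES}
        if self.qts is not None:
            d["qts"] = self.qts
        return pd.Series(d)


@dataclass
class SpotTable:
    """One antibody array: duplicate spots per protein plus control spots."""

    array_id: str
    spots: pd.DataFrame  # index protein, columns spot1, spot2 (NaN = missing)
    controls: dict = field(default_factory=dict)  # blank / negative / positive -> 1-D arrays

    def __post_init__(self) -> None:
        if not {"spot1", "spot2"}.issubset(self.spots.columns):
            raise ValueError("spot table needs 'spot1' and 'spot2' columns")
        for key in ("blank", "negative", "positive"):
            arr = np.asarray(self.controls.get(key, ()), dtype=float)
            if arr.size == 0:
                raise ValueError(f"array {self.array_id!r}: missing {key} control spots")
            self.controls[key] = arr


@dataclass
class GroundTruth:
    """Planted truth recorded by the synthetic generators."""

    deg_labels: pd.Series | None = None  # gene -> {"up", "down", "null"}
    phantom_bvtv: float | None = None    # fraction
    phantom_tbth: float | None = None    # pixels
    phantom_tbsp: float | None = None    # pixels
    hemolysis_samples: tuple = ()
    planted_fold_changes: dict | None = None
    pedsql_true_scores: pd.DataFrame | None = None
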