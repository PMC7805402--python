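"""Readers and writers for the pipeline's plain-text and image formats.

Conventions: TSV for expression matrices and vote results (gene ids in the
first column, sample ids in the header), CSV for spot/Cq/biomarker/PedsQL
tables, 16-bit PNG/TIFF for phantom images, Newick for dendrograms, JSON for
ground truth and run summaries. UTF-8 throughout, '.' decimal separator.
"""
from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, GroundTruth, RadiographROI, SpotTable

__all__ = [
    "read_expression",
    "write_expression",
    "read_spot_table",
    "write_spot_table",
    "read_cq_table",
    "write_cq_table",
    "read_roi_image",
    "write_roi_image",
    "write_ground_truth",
    "read_ground_truth",
    "write_newick",
    "write_json",
]


# -- expression ------------------------------------------------------------

def read_expression(matrix_path, pairing_path=None) -> ExpressionMatrix:
    """Read a genes x samples TSV plus optional pairing TSV.

    The matrix TSV has the gene id in its first column and sample ids in the
    header; the pairing TSV has columns sample_id, line_id, condition.
    Duplicate gene ids and pairing mismatches raise with the offending names.
    """
    values = pd.read_csv(matrix_path, sep="\t", index_col=0)
    if values.shape[1] == 0:
        raise ValueError(f"{matrix_path}: no sample columns found")
    non_numeric = [c for c in values.columns if not np.issubdtype(values[c].dtype, np.number)]
    if non_numeric:
        raise ValueError(f"{matrix_path}: non-numeric values in columns {non_numeric}")
    pairing = None
    if pairing_path is not None:
        pairing = pd.read_csv(pairing_path, sep="\t")
        if "sample_id" not in pairing.columns:
            raise ValueError(f"{pairing_path}: needs a sample_id column")
        pairing = pairing.set_index("sample_id")
    values.index.name = None
    return ExpressionMatrix(values=values, pairing=pairing)


def write_expression(m: ExpressionMatrix, matrix_path, pairing_path=None) -> None:
    m.values.to_csv(matrix_path, sep="\t", index_label="gene_id")
    if pairing_path is not None:
        if m.pairing is None:
            raise ValueError("matrix has no pairing to write")
        m.pairing.to_csv(pairing_path, sep="\t", index_label="sample_id")


# -- antibody arrays -------------------------------------------------------

def write_spot_table(t: SpotTable, spots_path, controls_path) -> None:
    t.spots.to_csv(spots_path, index_label="protein")
    rows = []
    for kind, arr in t.controls.items():
        rows += [{"control_type": kind, "intensity": float(v)} for v in np.asarray(arr)]
    pd.DataFrame(rows).to_csv(controls_path, index=False)


def read_spot_table(spots_path, controls_path, array_id: str | None = None) -> SpotTable:
    spots = pd.read_csv(spots_path, index_col="protein")
    spots.index.name = None
    ctl = pd.read_csv(controls_path)
    controls = {
        kind: grp["intensity"].to_numpy(dtype=float)
        for kind, grp in ctl.groupby("control_type")
    }
    return SpotTable(array_id=array_id or Path(spots_path).stem, spots=spots, controls=controls)


# -- miRNA -----------------------------------------------------------------

def write_cq_table(t: pd.DataFrame, path) -> None:
    t.to_csv(path, index_label="mirna")


def read_cq_table(path) -> pd.DataFrame:
    table = pd.read_csv(path, index_col="mirna")
    table.index.name = None
    return table


# -- images ----------------------------------------------------------------

def write_roi_image(roi: RadiographROI, path, sidecar=None) -> None:
    """Write the ROI as a 16-bit grayscale PNG/TIFF.

    Float intensities are mapped linearly onto the full uint16 range; the
    mapping (offset/scale) and pixel size go into a JSON sidecar (default:
    path + '.json') so reading restores the original values.
    """
    px = roi.pixels
    lo, hi = float(px.min()), float(px.max())
    scale = (hi - lo) / 65535.0 if hi > lo else 1.0
    data = np.round((px - lo) / scale).astype(np.uint16)
    iio.imwrite(Path(path), data)
    sidecar = Path(sidecar) if sidecar else Path(str(path) + ".json")
    sidecar.write_text(json.dumps({"pixel_size": roi.pixel_size, "offset": lo, "scale": scale}))


def read_roi_image(path, pixel_size: float | None = None, mask_path=None) -> RadiographROI:
    """Read a grayscale PNG/TIFF (with optional sidecar metadata and mask)."""
    data = np.asarray(iio.imread(Path(path))).astype(float)
    if data.ndim == 3:  # collapse an RGB(A) radiograph scan to one channel
        data = data[..., 0]
    sidecar = Path(str(path) + ".json")
    offset, scale = 0.0, 1.0
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        offset, scale = meta.get("offset", 0.0), meta.get("scale", 1.0)
        pixel_size = pixel_size or meta.get("pixel_size")
    if pixel_size is None:
        raise ValueError(f"{path}: pixel size not given and no sidecar found")
    mask = None
    if mask_path is not None:
        mask = np.asarray(iio.imread(Path(mask_path))) > 0
        if mask.ndim == 3:
            mask = mask[..., 0]
    return RadiographROI(pixels=data * scale + offset, pixel_size=float(pixel_size), mask=mask)


# -- misc ------------------------------------------------------------------

def write_ground_truth(truth: GroundTruth, path) -> None:
    payload: dict = {}
    if truth.deg_labels is not None:
        payload["deg_labels"] = truth.deg_labels.to_dict()
    for key in ("phantom_bvtv", "phantom_tbth", "phantom_tbsp"):
        if getattr(truth, key) is not None:
            payload[key] = getattr(truth, key)
    if truth.hemolysis_samples:
        payload["hemolysis_samples"] = list(truth.hemolysis_samples)
    Path(path).write_text(json.dumps(payload, sort_keys=True, indent=1))


def read_ground_truth(path) -> GroundTruth:
    payload = json.loads(Path(path).read_text())
    labels = payload.get("deg_labels")
    return GroundTruth(
        deg_labels=None if labels is None else pd.Series(labels, name="deg_label"),
        phantom_bvtv=payload.get("phantom_bvtv"),
        phantom_tbth=payload.get("phantom_tbth"),
        phantom_tbsp=payload.get("phantom_tbsp"),
        hemolysis_samples=tuple(payload.get("hemolysis_samples", ())),
    )


def write_newick(dendrogram, path) -> None:
    Path(path).write_text(dendrogram.to_newick() + "\n")


def write_json(payload: dict, path) -> None:
    """Deterministic JSON dump (sorted keys, no timestamps)."""
    Path(path).write_text(json.dumps(payload, sort_keys=True, indent=1) + "\n")
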