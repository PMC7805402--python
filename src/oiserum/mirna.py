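"""Circulating-miRNA Cq processing: hemolysis QC, normalization, row scaling.

The input is a table of qPCR quantification cycles (Cq), miRNAs in rows and
serum samples in columns. Red-cell contamination is screened with the
standard miR-451a / miR-23a-3p rule: miR-451a is erythrocyte-enriched, so a
large Cq gap Δ = Cq(miR-23a-3p) − Cq(miR-451a) marks hemolysis. Relative
expression is anchored to the RNA spike-in control added at extraction
(−ΔCq versus the spike-in, so higher means more abundant), which also makes
the values invariant to per-sample global Cq shifts. For heatmaps, rows are
optionally global-mean normalized (per-sample mean removed) and then scaled
to zero mean, unit variance.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "MiRNAConfig",
    "hemolysis_check",
    "spikein_normalize",
    "global_mean_normalize",
    "heatmap_scale",
]

PASS, FAIL, UNDETERMINED = "pass", "fail", "undetermined"


@dataclass
class MiRNAConfig:
    """hemolysis_delta_threshold: Cq cycles; samples fail the check when
    Cq(miR-23a-3p) − Cq(miR-451a) strictly exceeds it (7 cycles is the
    field-standard cut-off for this marker pair). spikein_id names the
    normalization spike-in row; the marker ids are configurable because
    panel nomenclature varies."""

    hemolysis_delta_threshold: float = 7.0
    spikein_id: str = "UniSp3"
    mir451a_id: str = "hsa-miR-451a"
    mir23a_id: str = "hsa-miR-23a-3p"

    def __post_init__(self) -> None:
        if not self.hemolysis_delta_threshold > 0:
            raise ValueError("hemolysis threshold must be > 0")


def _check_table(t: pd.DataFrame) -> pd.DataFrame:
    if not isinstance(t, pd.DataFrame) or t.size == 0:
        raise ValueError("Cq table must be a non-empty DataFrame (miRNA x sample)")
    arr = t.to_numpy(dtype=float)
    if np.nanmin(arr) <= 0:
        raise ValueError("Cq values must be positive")
    return t.astype(float)


def hemolysis_check(t: pd.DataFrame, cfg: MiRNAConfig | None = None) -> pd.Series:
    """Per-sample hemolysis QC: 'pass', 'fail', or 'undetermined'.

    Fails when Δ = Cq(miR-23a-3p) − Cq(miR-451a) > threshold (strict);
    a sample with either marker missing is 'undetermined'.
    """
    cfg = cfg or MiRNAConfig()
    t = _check_table(t)
    for marker in (cfg.mir451a_id, cfg.mir23a_id):
        if marker not in t.index:
            raise ValueError(f"marker row {marker!r} missing from Cq table")
    delta = t.loc[cfg.mir23a_id] - t.loc[cfg.mir451a_id]
    out = pd.Series(
        np.where(delta.isna(), UNDETERMINED, np.where(delta > cfg.hemolysis_delta_threshold, FAIL, PASS)),
        index=t.columns,
        name="hemolysis_qc",
    )
    return out


def spikein_normalize(t: pd.DataFrame, cfg: MiRNAConfig | None = None) -> pd.DataFrame:
    """Relative expression as −ΔCq versus the spike-in control.

    expression = −(Cq_miRNA − Cq_spikein) per sample, so a miRNA amplifying
    one cycle earlier than the spike-in scores +1. Samples without a
    spike-in Cq are dropped with a warning; the spike-in row itself is
    removed from the output.
    """
    cfg = cfg or MiRNAConfig()
    t = _check_table(t)
    if cfg.spikein_id not in t.index:
        raise ValueError(f"spike-in row {cfg.spikein_id!r} missing from Cq table")
    spike = t.loc[cfg.spikein_id]
    bad = list(spike.index[spike.isna()])
    if bad:
        warnings.warn(f"samples without spike-in Cq excluded: {bad}", stacklevel=2)
        t = t.drop(columns=bad)
        spike = spike.drop(index=bad)
    expr = -(t.drop(index=cfg.spikein_id) - spike)
    return expr


def global_mean_normalize(expr: pd.DataFrame) -> pd.DataFrame:
    """Remove each sample's mean expression (global-mean normalization)."""
    return expr - expr.mean(axis=0, skipna=True)


def heatmap_scale(expr: pd.DataFrame) -> pd.DataFrame:
    """Unit-variance scaling per miRNA row: subtract the row mean, divide by
    the row standard deviation (ddof=1). Constant rows are dropped with a
    warning rather than producing NaN. Needs at least two samples."""
    if expr.shape[1] < 2:
        raise ValueError("row scaling needs at least two samples")
    sd = expr.std(axis=1, ddof=1)
    constant = list(expr.index[(sd == 0) | sd.isna()])
    if constant:
        warnings.warn(f"constant rows dropped from heatmap scaling: {constant}", stacklevel=2)
        expr = expr.drop(index=constant)
        sd = sd.drop(index=constant)
    return expr.sub(expr.mean(axis=1), axis=0).div(sd, axis=0)
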