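"""The umbrella pipeline: run configured stages and write a summary JSON.

A run configuration (usually loaded from YAML) names the stages to execute
and their parameters; each stage writes its outputs under ``outdir`` and
contributes a block to a machine-readable summary. All randomness flows from
seeds in the configuration, so the same configuration reproduces the same
outputs byte for byte.
"""
from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml

from . import deg, hrqol, io, mirna, serum_array, synthdata, trabecular
from .containers import ExpressionMatrix

__all__ = ["run_pipeline", "load_config", "validate_summary", "SUMMARY_SCHEMA"]

#: structural schema of the summary JSON: stage -> {key: required type(s)}
SUMMARY_SCHEMA: dict[str, dict[str, type | tuple]] = {
    "deg": {"n_selected": int, "n_up": int, "n_down": int, "params": dict},
    "trabecular": {"images": list},
    "array": {"n_common_upregulated": int, "common_upregulated": list},
    "mirna": {"hemolysis": dict, "n_mirnas": int, "n_samples": int},
    "pedsql": {"n_respondents": int, "scores": list},
    "simulate": {"outputs": list},
}


class StageError(RuntimeError):
    """A stage failed; carries the stage name in the message."""


def load_config(path) -> dict:
    cfg = yaml.safe_load(Path(path).read_text())
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: run configuration must be a mapping")
    return cfg


def validate_summary(summary: dict) -> None:
    """Check the summary against the shipped structural schema."""
    for stage, block in summary.items():
        expected = SUMMARY_SCHEMA.get(stage)
        if expected is None:
            raise ValueError(f"summary has unknown stage block {stage!r}")
        for key, typ in expected.items():
            if key not in block:
                raise ValueError(f"summary[{stage!r}] lacks required key {key!r}")
            if not isinstance(block[key], typ):
                raise ValueError(f"summary[{stage!r}][{key!r}] has wrong type")


def _stage_simulate(cfg: dict, outdir: Path) -> dict:
    outputs = []
    if "expression" in cfg:
        sim_cfg = synthdata.SimExpressionConfig(**cfg["expression"])
        matrix, truth = synthdata.simulate_paired_expression(sim_cfg)
        io.write_expression(matrix, outdir / "expression.tsv", outdir / "pairing.tsv")
        io.write_ground_truth(truth, outdir / "expression_truth.json")
        outputs += ["expression.tsv", "pairing.tsv", "expression_truth.json"]
    if "phantom" in cfg:
        sim_cfg = synthdata.SimPhantomConfig(**cfg["phantom"])
        roi, truth = synthdata.simulate_phantom(sim_cfg)
        io.write_roi_image(roi, outdir / "phantom.png")
        io.write_ground_truth(truth, outdir / "phantom_truth.json")
        outputs += ["phantom.png", "phantom_truth.json"]
    return {"outputs": sorted(outputs)}


def _stage_deg(cfg: dict, outdir: Path) -> dict:
    m = io.read_expression(cfg["matrix"], cfg["pairs"])
    vote_cfg = deg.VoteConfig(
        theta_vote=cfg.get("theta_vote", 0.1),
        min_votes=cfg.get("min_votes", 9),
        alpha=cfg.get("alpha", 0.05),
    )
    transformed = deg.log2p1(deg.quantile_normalize(m))
    result = deg.democratic_vote(transformed, vote_cfg)
    result.to_csv(outdir / "vote_result.tsv", sep="\t", index_label="gene")
    tree = deg.upgma_cluster(transformed)
    io.write_newick(tree, outdir / "samples.nwk")
    n_up = int((result["direction"] == "up").sum())
    n_down = int((result["direction"] == "down").sum())
    return {
        "n_selected": n_up + n_down,
        "n_up": n_up,
        "n_down": n_down,
        "params": {
            "theta_vote": vote_cfg.theta_vote,
            "min_votes": vote_cfg.min_votes,
            "alpha": vote_cfg.alpha,
        },
    }


def _stage_trabecular(cfg: dict, outdir: Path) -> dict:
    reference = None
    if cfg.get("reference"):
        reference = pd.read_csv(cfg["reference"])
    rows, blocks = [], []
    for image in cfg["images"]:
        roi = io.read_roi_image(
            image, pixel_size=cfg.get("pixel_size"), mask_path=cfg.get("mask")
        )
        bm = trabecular.analyze_roi(
            roi, reference=reference, kernel_scale=cfg.get("kernel_scale")
        )
        series = bm.as_series()
        series["image"] = str(image)
        blocks.append(series)
        rows.append({"image": str(image), **{k: float(v) for k, v in bm.as_series().items()}})
    pd.DataFrame(blocks).set_index("image").to_csv(outdir / "biomarkers.csv")
    return {"images": rows}


def _stage_array(cfg: dict, outdir: Path) -> dict:
    arr_cfg = serum_array.ArrayConfig(
        fc_threshold=cfg.get("fc_threshold", 1.3), floor=cfg.get("floor")
    )
    profiles = {}
    for entry in [cfg["basal"], *cfg["timepoints"]]:
        t = io.read_spot_table(entry["spots"], entry["controls"], entry.get("array_id"))
        profiles[t.array_id] = serum_array.normalize_array(t)
    basal_id = cfg.get("basal_id") or Path(cfg["basal"]["spots"]).stem
    fc = serum_array.fold_change_vs_basal(pd.DataFrame(profiles), basal_id, arr_cfg)
    fc.to_csv(outdir / "fold_changes.csv")
    common = sorted(serum_array.common_upregulated([fc])) if fc.columns.get_level_values(0).nunique() >= 2 else sorted(
        serum_array.upregulated_set(fc, fc.columns.get_level_values(0)[0])
    )
    (outdir / "common_upregulated.txt").write_text("\n".join(common) + "\n")
    return {"n_common_upregulated": len(common), "common_upregulated": common}


def _stage_mirna(cfg: dict, outdir: Path) -> dict:
    mi_cfg = mirna.MiRNAConfig(
        hemolysis_delta_threshold=cfg.get("hemolysis_delta_threshold", 7.0),
        spikein_id=cfg.get("spikein_id", "UniSp3"),
    )
    table = io.read_cq_table(cfg["cq"])
    qc = mirna.hemolysis_check(table, mi_cfg)
    expr = mirna.spikein_normalize(table, mi_cfg)
    scaled = mirna.heatmap_scale(mirna.global_mean_normalize(expr))
    order = deg.upgma_cluster(scaled.T).labels  # row ordering via UPGMA on miRNAs
    scaled = scaled.loc[order]
    io.write_json({"hemolysis": qc.to_dict()}, outdir / "mirna_qc.json")
    expr.to_csv(outdir / "mirna_normalized.csv", index_label="mirna")
    scaled.to_csv(outdir / "mirna_heatmap.csv", index_label="mirna")
    return {
        "hemolysis": qc.to_dict(),
        "n_mirnas": int(expr.shape[0]),
        "n_samples": int(expr.shape[1]),
    }


def _stage_pedsql(cfg: dict, outdir: Path) -> dict:
    responses = pd.read_csv(cfg["responses"], index_col=0)
    scores = hrqol.score_table(responses)
    scores.to_csv(outdir / "pedsql_scores.csv", index_label="respondent_id")
    return {
        "n_respondents": int(len(scores)),
        "scores": [
            {"respondent_id": str(idx), **{k: (None if pd.isna(v) else v) for k, v in row.items() if k != "respondent"}}
            for idx, row in scores.iterrows()
        ],
    }


_STAGES = {
    "simulate": _stage_simulate,
    "deg": _stage_deg,
    "trabecular": _stage_trabecular,
    "array": _stage_array,
    "mirna": _stage_mirna,
    "pedsql": _stage_pedsql,
}


def run_pipeline(cfg: dict, outdir=None) -> dict:
    """Execute the configured stages in order; returns the summary dict.

    ``cfg`` maps stage names (see ``SUMMARY_SCHEMA``) to their parameters;
    an optional ``outdir`` key (overridden by the argument) locates all
    outputs. The summary is also written to ``outdir/summary.json``.
    """
    outdir = Path(outdir or cfg.get("outdir", "."))
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {}
    for stage in cfg:
        if stage == "outdir":
            continue
        runner = _STAGES.get(stage)
        if runner is None:
            raise StageError(f"[{stage}] unknown stage")
        try:
            summary[stage] = runner(cfg[stage], outdir)
        except StageError:
            raise
        except Exception as exc:  # noqa: BLE001 - stage-tagged rethrow
            raise StageError(f"[{stage}] {exc}") from exc
    validate_summary(summary)
    io.write_json(summary, outdir / "summary.json")
    return summary
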