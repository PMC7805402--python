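"""Seeded generators for every input the pipeline consumes.

Each generator is a pure function of its configuration (including the seed)
and records the planted ground truth, so every downstream stage can be
tested against known answers without any external data:

* paired expression matrices with line-specific baselines and a planted
  fraction of up/down genes at a fixed log2 effect size (simulated on the
  log2 scale, then exponentiated to FPKM-like values so the pipeline's
  log2(x+1) re-transform round-trips);
* rod-lattice bone phantoms whose BV/TV, rod width and pore width are known
  analytically, optionally degraded by a linear illumination gradient and
  Gaussian noise (clipped at zero);
* antibody-array spot tables with duplicate spots, control spots and planted
  fold changes recoverable after control normalization;
* miRNA Cq tables with a spike-in row and an optional planted hemolysis
  signature;
* PedsQL response tables with known true scores.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, GroundTruth, RadiographROI, SpotTable
from .hrqol import DOMAINS, N_ITEMS, PedsQLResponse, score
from .mirna import MiRNAConfig

__all__ = [
    "SimExpressionConfig",
    "SimPhantomConfig",
    "simulate_paired_expression",
    "simulate_phantom",
    "simulate_spot_table",
    "simulate_cq_table",
    "simulate_pedsql_responses",
]


@dataclass
class SimExpressionConfig:
    """Paired-design expression simulation.

    frac_up / frac_down genes shift by ±effect_size (log2) in every line's
    post-treatment column; line_sd spreads per-gene, per-line baselines and
    noise_sd is the per-measurement log2 noise.
    """

    n_genes: int = 1000
    n_lines: int = 10
    frac_up: float = 0.1
    frac_down: float = 0.1
    effect_size: float = 0.5
    line_sd: float = 0.5
    noise_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or self.n_lines <= 0:
            raise ValueError("n_genes and n_lines must be positive")
        if not (0 <= self.frac_up <= 1 and 0 <= self.frac_down <= 1):
            raise ValueError("fractions must lie in [0, 1]")
        if self.frac_up + self.frac_down > 1:
            raise ValueError("frac_up + frac_down must not exceed 1")
        if min(self.line_sd, self.noise_sd) < 0 or self.effect_size < 0:
            raise ValueError("standard deviations and effect size must be >= 0")


def simulate_paired_expression(cfg: SimExpressionConfig) -> tuple[ExpressionMatrix, GroundTruth]:
    """Simulate a basal/post paired expression matrix with planted DEGs."""
    rng = np.random.default_rng(cfg.seed)
    genes = [f"g{i + 1:05d}" for i in range(cfg.n_genes)]
    lines = [f"L{j + 1:02d}" for j in range(cfg.n_lines)]

    n_up = int(round(cfg.frac_up * cfg.n_genes))
    n_down = int(round(cfg.frac_down * cfg.n_genes))
    labels = np.array(["null"] * cfg.n_genes, dtype=object)
    positions = rng.permutation(cfg.n_genes)
    labels[positions[:n_up]] = "up"
    labels[positions[n_up : n_up + n_down]] = "down"
    delta = np.where(labels == "up", cfg.effect_size, np.where(labels == "down", -cfg.effect_size, 0.0))

    base = rng.uniform(3.0, 9.0, size=cfg.n_genes)
    line_base = base[:, None] + rng.normal(0.0, cfg.line_sd, size=(cfg.n_genes, cfg.n_lines))
    log_basal = line_base + rng.normal(0.0, cfg.noise_sd, size=line_base.shape)
    log_post = line_base + delta[:, None] + rng.normal(0.0, cfg.noise_sd, size=line_base.shape)

    cols, data = [], []
    for j, line in enumerate(lines):
        cols += [f"{line}_basal", f"{line}_post"]
        data += [log_basal[:, j], log_post[:, j]]
    log_values = np.clip(np.stack(data, axis=1), 0.0, None)
    values = pd.DataFrame(np.exp2(log_values) - 1.0, index=genes, columns=cols)
    pairing = pd.DataFrame(
        {
            "line_id": [c.rsplit("_", 1)[0] for c in cols],
            "condition": [c.rsplit("_", 1)[1] for c in cols],
        },
        index=pd.Index(cols, name="sample_id"),
    )
    truth = GroundTruth(deg_labels=pd.Series(labels, index=genes, name="deg_label"))
    return ExpressionMatrix(values=values, pairing=pairing), truth


@dataclass
class SimPhantomConfig:
    """Rod-lattice trabecular phantom.

    Straight rods of ``rod_width`` pixels repeat every ``rod_spacing``
    pixels (centered within each period so the lattice never touches the
    image border), on a background; the image is foreground/background
    levels times the lattice mask, optionally shaded by a linear
    illumination ramp of peak-to-peak fraction ``illum_gradient`` and
    degraded by Gaussian noise clipped at zero. For an image size divisible
    by the spacing, BV/TV is rod_width/rod_spacing exactly (grid
    orientation: 1 − (1 − w/s)²).
    """

    image_size: int = 128
    rod_width: int = 4
    rod_spacing: int = 16
    orientation: str = "horizontal"  # horizontal | vertical | grid
    illum_gradient: float = 0.0
    noise_sd: float = 0.0
    pixel_size: float = 0.1  # mm / pixel
    foreground_level: float = 1.0
    background_level: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rod_width >= self.rod_spacing:
            raise ValueError("rod_width must be smaller than rod_spacing")
        if self.image_size <= self.rod_spacing:
            raise ValueError("image_size must exceed rod_spacing")
        if self.orientation not in ("horizontal", "vertical", "grid"):
            raise ValueError("orientation must be horizontal, vertical or grid")
        if self.noise_sd < 0 or self.illum_gradient < 0:
            raise ValueError("noise_sd and illum_gradient must be >= 0")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be > 0")
        if not self.foreground_level > self.background_level:
            raise ValueError("foreground level must exceed background level")


def lattice_mask(cfg: SimPhantomConfig) -> np.ndarray:
    """The noise-free boolean rod lattice of a phantom configuration."""
    n, w, s = cfg.image_size, cfg.rod_width, cfg.rod_spacing
    offset = (s - w) // 2
    idx = np.arange(n)
    band = ((idx - offset) % s) < w
    band &= idx >= offset  # keep the lattice centered: no partial rod at the origin
    rows = np.broadcast_to(band[:, None], (n, n))
    cols = np.broadcast_to(band[None, :], (n, n))
    if cfg.orientation == "horizontal":
        return rows.copy()
    if cfg.orientation == "vertical":
        return cols.copy()
    return rows | cols


def simulate_phantom(cfg: SimPhantomConfig) -> tuple[RadiographROI, GroundTruth]:
    """Render a phantom radiograph ROI and its analytic ground truth."""
    rng = np.random.default_rng(cfg.seed)
    mask = lattice_mask(cfg)
    img = np.where(mask, cfg.foreground_level, cfg.background_level).astype(float)
    if cfg.illum_gradient > 0:
        ramp = 1.0 + cfg.illum_gradient * (
            np.linspace(0.0, 1.0, cfg.image_size)[None, :] - 0.5
        )
        img = img * ramp
    if cfg.noise_sd > 0:
        img = img + rng.normal(0.0, cfg.noise_sd, size=img.shape)
    img = np.clip(img, 0.0, None)
    truth = GroundTruth(
        phantom_bvtv=float(mask.mean()),
        phantom_tbth=float(cfg.rod_width),
        phantom_tbsp=float(cfg.rod_spacing - cfg.rod_width),
    )
    return RadiographROI(pixels=img, pixel_size=cfg.pixel_size), truth


def simulate_spot_table(
    n_proteins: int,
    planted_fc_map: dict,
    control_levels: dict,
    seed: int = 0,
    array_ids: tuple[str, ...] = ("basal", "post"),
    basal_id: str = "basal",
    noise_sd: float = 0.0,
    gains: dict | None = None,
) -> dict[str, SpotTable]:
    """Simulate one spot table per array with planted fold changes vs basal.

    ``planted_fc_map`` maps protein id -> fold change (applied to every
    non-basal array) or array id -> {protein: fold change}. All planted fold
    changes must be positive. ``control_levels`` must define blank, negative
    and positive intensities; ``gains`` optionally applies a global scanner
    gain per array (normalization must undo it). Duplicate spots get
    independent multiplicative Gaussian noise of sd ``noise_sd``.
    """
    for key in ("blank", "negative", "positive"):
        if key not in control_levels:
            raise ValueError(f"control_levels must define {key!r}")
    if basal_id not in array_ids:
        raise ValueError("array_ids must include the basal array")
    per_array = all(isinstance(v, dict) for v in planted_fc_map.values()) and planted_fc_map
    rng = np.random.default_rng(seed)
    proteins = [f"P{i + 1:04d}" for i in range(n_proteins)]
    u = rng.uniform(0.1, 0.9, size=n_proteins)  # true normalized basal levels

    blank = float(control_levels["blank"])
    negative = float(control_levels["negative"])
    positive = float(control_levels["positive"])
    background = (blank + negative) / 2.0
    scale = positive - background
    if scale <= 0:
        raise ValueError("positive control level must exceed the background")

    tables: dict[str, SpotTable] = {}
    for array_id in array_ids:
        fc = np.ones(n_proteins)
        if array_id != basal_id:
            fc_of = planted_fc_map.get(array_id, {}) if per_array else planted_fc_map
            for i, p in enumerate(proteins):
                if p in fc_of:
                    if not fc_of[p] > 0:
                        raise ValueError("planted fold changes must be positive")
                    fc[i] = fc_of[p]
        gain = float((gains or {}).get(array_id, 1.0))
        true_intensity = (background + u * fc * scale) * gain
        spots = np.repeat(true_intensity[:, None], 2, axis=1)
        if noise_sd > 0:
            spots = spots * (1.0 + rng.normal(0.0, noise_sd, size=spots.shape))
        tables[array_id] = SpotTable(
            array_id=array_id,
            spots=pd.DataFrame(spots, index=proteins, columns=["spot1", "spot2"]),
            controls={
                "blank": np.full(3, blank * gain),
                "negative": np.full(3, negative * gain),
                "positive": np.full(3, positive * gain),
            },
        )
    return tables


def simulate_cq_table(
    n_mirnas: int,
    n_samples: int,
    hemolysis_samples: tuple[str, ...] = (),
    seed: int = 0,
    noise_sd: float = 0.0,
    hemolysis_shift: float = 8.0,
    cfg: MiRNAConfig | None = None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate a Cq table (miRNA x sample) with spike-in and QC marker rows.

    Clean samples sit ~2 cycles apart on the hemolysis markers (well under
    the 7-cycle threshold); planted hemolysis samples get their miR-451a Cq
    lowered by ``hemolysis_shift`` cycles beyond that, pushing the marker
    difference over the threshold. The spike-in Cq is constant up to noise,
    and every sample carries a global Cq offset (pipetting/input variation)
    that spike-in normalization must cancel.
    """
    if n_samples <= 0:
        raise ValueError("n_samples must be positive")
    cfg = cfg or MiRNAConfig()
    rng = np.random.default_rng(seed)
    samples = [f"S{j + 1:02d}" for j in range(n_samples)]
    unknown = sorted(set(hemolysis_samples) - set(samples))
    if unknown:
        raise ValueError(f"hemolysis_samples not in the sample set: {unknown}")
    extra = [f"hsa-miR-{100 + i}-5p" for i in range(n_mirnas)]
    rows = [cfg.spikein_id, cfg.mir451a_id, cfg.mir23a_id] + extra

    base = {cfg.spikein_id: 19.0, cfg.mir451a_id: 24.0, cfg.mir23a_id: 26.0}
    for i, m in enumerate(extra):
        base[m] = float(rng.uniform(22.0, 33.0))
    sample_offset = rng.normal(0.0, 0.5, size=n_samples)

    table = pd.DataFrame(index=rows, columns=samples, dtype=float)
    for j, s in enumerate(samples):
        cq = np.array([base[m] for m in rows]) + sample_offset[j]
        if s in hemolysis_samples:
            cq[rows.index(cfg.mir451a_id)] -= hemolysis_shift + (cfg.hemolysis_delta_threshold - 2.0)
        if noise_sd > 0:
            cq = cq + rng.normal(0.0, noise_sd, size=len(cq))
        table[s] = cq
    truth = GroundTruth(hemolysis_samples=tuple(hemolysis_samples))
    return table, truth


def simulate_pedsql_responses(
    n_respondents: int,
    seed: int = 0,
    missing_rate: float = 0.0,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate PedsQL questionnaires and their true (pre-missingness) scores."""
    if n_respondents <= 0:
        raise ValueError("n_respondents must be positive")
    if not 0 <= missing_rate < 0.5:
        raise ValueError("missing_rate must be in [0, 0.5)")
    rng = np.random.default_rng(seed)
    rows, truths = {}, {}
    for k in range(n_respondents):
        rid = f"R{k + 1:02d}"
        severity = rng.uniform(0.0, 1.0)
        items = rng.binomial(4, severity, size=N_ITEMS).astype(float)
        truths[rid] = score(PedsQLResponse(items=list(items)))
        if missing_rate > 0:
            drop = rng.random(N_ITEMS) < missing_rate
            items[drop] = np.nan
        rows[rid] = {f"item_{i + 1}": items[i] for i in range(N_ITEMS)}
        rows[rid]["respondent"] = "self" if k % 2 == 0 else "proxy"
    responses = pd.DataFrame.from_dict(rows, orient="index")
    truth = GroundTruth(pedsql_true_scores=pd.DataFrame.from_dict(truths, orient="index"))
    return responses, truth
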