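"""Seeded generators for single-cell and bulk fixtures.

The single-cell generator plants subgroup markers, mitochondrial
content, and contiguous chromosomal copy-number segments confined to
malignant cells. The bulk generator plants signature-gene shifts in
responders, batch effects, and censored exponential survival. One
global seed drives independent sub-streams per stage, so adding a
stage never perturbs earlier draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
import yaml

from immunosig.errors import ConfigError
from immunosig.io_formats import (
    BulkCohort,
    ExpressionMatrix,
    GeneSignature,
    sort_genes_by_position,
)

GROUPS = ("PD-pre", "NPD-pre", "NPD-post")


@dataclass
class CnvSegment:
    """Contiguous copy-number segment applied to malignant-cell gene means."""

    chromosome: str
    start_gene_index: int  # offset within the chromosome's gene block
    n_genes: int
    copy_ratio: float

    def __post_init__(self) -> None:
        if self.copy_ratio <= 0:
            raise ConfigError("copy_ratio must be > 0")
        if self.n_genes <= 0:
            raise ConfigError("segment n_genes must be positive")


@dataclass
class SynthConfig:
    """All knobs for both generators; see module docstring."""

    seed: int = 0
    # --- single cell ---
    n_patients_per_group: Mapping[str, int] = field(
        default_factory=lambda: {"PD-pre": 3, "NPD-pre": 8, "NPD-post": 8}
    )
    cells_per_patient: int = 100
    n_genes: int = 1000
    n_mito_genes: int = 10
    n_chromosomes: int = 5
    # subgroup -> fraction, per group; subgroup label "TYPE_SUB" implies cell type
    cell_type_fractions: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {
            g: {
                "MM_Immune": 0.30,
                "B_CD74": 0.0 if g == "PD-pre" else 0.15,
                "DC_cDC2": 0.15 if g != "PD-pre" else 0.20,
                "CAF_iCAF": 0.15,
                "CD8T": 0.25 if g == "PD-pre" else 0.15,
                "NK": 0.10 if g == "PD-pre" else 0.10,
            }
            for g in GROUPS
        }
    )
    # subgroup -> (n marker genes, log2 fold change)
    marker_spec: Mapping[str, tuple[int, float]] = field(
        default_factory=lambda: {
            "MM_Immune": (20, 2.0),
            "B_CD74": (20, 2.0),
            "DC_cDC2": (20, 2.0),
            "CAF_iCAF": (20, 2.0),
            "CD8T": (20, 2.0),
            "NK": (20, 2.0),
        }
    )
    cnv_segments: Sequence[CnvSegment] = field(default_factory=list)
    malignant_cell_type: str = "MM"
    mito_fraction: float = 0.03
    # negative binomial baseline: per-gene means lognormal, common dispersion
    baseline_log_mean: float = -1.0
    baseline_log_sd: float = 1.0
    nb_dispersion: float = 0.5  # variance = mu + dispersion * mu^2
    # --- bulk ---
    bulk_n_samples: int = 244
    bulk_n_genes: int = 2000
    bulk_npd_fraction: float = 0.5
    bulk_effect: float = 1.0  # NPD mean shift (SD units) on signature genes
    batch_shifts: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {"cohortA": (0.0, 1.0), "cohortB": (1.0, 1.0)}
    )
    survival_model: Mapping[str, float] = field(
        default_factory=lambda: {"PD": 1 / 10.0, "NPD": 1 / 40.0}
    )  # exponential rates (1/months) per response class
    censoring_rate: float = 0.2

    def __post_init__(self) -> None:
        for group, fractions in self.cell_type_fractions.items():
            total = float(sum(fractions.values()))
            if abs(total - 1.0) > 1e-9:
                raise ConfigError(
                    f"cell-type fractions for group {group!r} sum to {total}, not 1"
                )
        for key in ("cells_per_patient", "n_genes", "bulk_n_samples", "bulk_n_genes"):
            if getattr(self, key) <= 0:
                raise ConfigError(f"{key} must be positive")
        for seg in self.cnv_segments:
            if not isinstance(seg, CnvSegment):
                raise ConfigError("cnv_segments entries must be CnvSegment")
        if self.bulk_effect < 0:
            raise ConfigError("bulk_effect must be >= 0 (NPD-up convention)")
        if not 0 <= self.censoring_rate <= 1:
            raise ConfigError("censoring_rate must be in [0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SynthConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "cnv_segments" in raw:
            raw["cnv_segments"] = [CnvSegment(**seg) for seg in raw["cnv_segments"]]
        if "marker_spec" in raw:
            raw["marker_spec"] = {
                k: tuple(v) for k, v in raw["marker_spec"].items()
            }
        if "batch_shifts" in raw:
            raw["batch_shifts"] = {
                k: tuple(v) for k, v in raw["batch_shifts"].items()
            }
        return cls(**raw)


def _cell_type_of(subgroup: str) -> str:
    return subgroup.split("_")[0]


def _streams(seed: int, names: Sequence[str]) -> dict[str, np.random.Generator]:
    root = np.random.SeedSequence(seed)
    children = root.spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def _nb_draw(
    rng: np.random.Generator, mean: np.ndarray, dispersion: float
) -> np.ndarray:
    """Negative binomial with variance mu + dispersion*mu^2 (gamma-Poisson)."""
    if dispersion <= 0:
        return rng.poisson(mean)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean * dispersion)
    return rng.poisson(lam)


# ---------------------------------------------------------------------------
# Single-cell generator
# ---------------------------------------------------------------------------


def gen_gene_annotation(config: SynthConfig) -> tuple[pd.DataFrame, dict]:
    """Gene universe: named genes laid out contiguously on chromosomes.

    Mito genes live on MT. Marker blocks are assigned disjoint gene
    ranges per subgroup, recorded in the returned layout dict.
    """
    n_regular = config.n_genes - config.n_mito_genes
    if n_regular <= 0:
        raise ConfigError("n_genes must exceed n_mito_genes")
    gene_ids = [f"G{i + 1:05d}" for i in range(n_regular)]
    chroms = [str(c + 1) for c in range(config.n_chromosomes)]
    per_chrom = int(np.ceil(n_regular / config.n_chromosomes))
    rows = []
    for i, g in enumerate(gene_ids):
        chrom = chroms[min(i // per_chrom, config.n_chromosomes - 1)]
        rows.append((g, chrom, 1000 * (i % per_chrom) + 1, False))
    for j in range(config.n_mito_genes):
        rows.append((f"MT-{j + 1}", "MT", 1000 * j + 1, True))
    annotation = pd.DataFrame(
        rows, columns=["gene_id", "chromosome", "start", "is_mito"]
    )
    annotation = sort_genes_by_position(annotation)

    # disjoint marker blocks, skipping genes inside CNV segments
    cnv_gene_idx: set[int] = set()
    chrom_offsets = {
        c: int(np.flatnonzero((annotation["chromosome"] == c).values)[0])
        for c in chroms
    }
    for seg in config.cnv_segments:
        base = chrom_offsets[str(seg.chromosome)]
        cnv_gene_idx.update(range(base + seg.start_gene_index,
                                  base + seg.start_gene_index + seg.n_genes))
    marker_blocks: dict[str, list[str]] = {}
    cursor = 0
    regular_idx = [
        i for i in range(len(annotation)) if not annotation["is_mito"].iloc[i]
    ]
    usable = [i for i in regular_idx if i not in cnv_gene_idx]
    for subgroup, (n_markers, _) in config.marker_spec.items():
        block = usable[cursor : cursor + n_markers]
        if len(block) < n_markers:
            raise ConfigError("not enough genes for the requested marker blocks")
        marker_blocks[subgroup] = [annotation["gene_id"].iloc[i] for i in block]
        cursor += n_markers
    layout = {"marker_blocks": marker_blocks, "cnv_gene_indices": sorted(cnv_gene_idx)}
    return annotation, layout


def gen_single_cell(
    config: SynthConfig,
) -> tuple[ExpressionMatrix, pd.DataFrame, pd.DataFrame]:
    """Generate (ExpressionMatrix, cell annotation, gene annotation).

    Cell annotation columns: cell_id, patient_id, group, cell_type,
    subgroup. Identical seed gives bit-identical output.
    """
    rngs = _streams(config.seed, ["means", "labels", "counts", "bulk", "survival"])
    annotation, layout = gen_gene_annotation(config)
    gene_ids = list(annotation["gene_id"])
    n_genes = len(gene_ids)
    gene_pos = {g: i for i, g in enumerate(gene_ids)}
    is_mito = annotation["is_mito"].values

    # baseline means; mito means rescaled to hit the target count fraction
    mu = np.exp(
        rngs["means"].normal(config.baseline_log_mean, config.baseline_log_sd, n_genes)
    )
    if is_mito.any() and config.mito_fraction > 0:
        target = config.mito_fraction / (1 - config.mito_fraction)
        mu[is_mito] *= target * mu[~is_mito].sum() / mu[is_mito].sum()

    # cell labels
    cells, patients, groups, cell_types, subgroups = [], [], [], [], []
    pat_counter = 0
    for group in GROUPS:
        n_patients = int(config.n_patients_per_group.get(group, 0))
        fractions = config.cell_type_fractions[group]
        names = list(fractions)
        probs = np.array([fractions[s] for s in names], dtype=float)
        for _ in range(n_patients):
            pat_counter += 1
            pid = f"P{pat_counter:02d}"
            draw = rngs["labels"].choice(
                len(names), size=config.cells_per_patient, p=probs
            )
            for j, k in enumerate(draw):
                cells.append(f"{pid}_C{j + 1:04d}")
                patients.append(pid)
                groups.append(group)
                subgroups.append(names[k])
                cell_types.append(_cell_type_of(names[k]))
    n_cells = len(cells)
    cell_ann = pd.DataFrame(
        {
            "cell_id": cells,
            "patient_id": patients,
            "group": groups,
            "cell_type": cell_types,
            "subgroup": subgroups,
        }
    )

    # per-cell mean matrix adjustments: markers and CNV segments
    counts = np.empty((n_genes, n_cells), dtype=np.int64)
    marker_blocks = layout["marker_blocks"]
    cnv_idx = np.array(layout["cnv_gene_indices"], dtype=int)
    seg_ratio = np.ones(n_genes)
    chrom_offsets = {}
    for c in annotation["chromosome"].unique():
        chrom_offsets[c] = int(
            np.flatnonzero((annotation["chromosome"] == c).values)[0]
        )
    for seg in config.cnv_segments:
        base = chrom_offsets[str(seg.chromosome)]
        seg_ratio[base + seg.start_gene_index : base + seg.start_gene_index + seg.n_genes] = (
            seg.copy_ratio
        )

    marker_mult = {}
    for subgroup, (_, log2fc) in config.marker_spec.items():
        idx = np.array([gene_pos[g] for g in marker_blocks[subgroup]], dtype=int)
        marker_mult[subgroup] = (idx, 2.0 ** log2fc)

    malignant = cell_ann["cell_type"].values == config.malignant_cell_type
    rng_counts = rngs["counts"]
    for j in range(n_cells):
        mu_j = mu.copy()
        sub = subgroups[j]
        if sub in marker_mult:
            idx, mult = marker_mult[sub]
            mu_j[idx] *= mult
        if malignant[j] and len(cnv_idx):
            mu_j *= seg_ratio
        counts[:, j] = _nb_draw(rng_counts, mu_j, config.nb_dispersion)

    matrix = ExpressionMatrix(
        gene_ids=gene_ids,
        cell_ids=cells,
        counts=sp.csr_matrix(counts),
        layer_tag="counts",
    )
    return matrix, cell_ann, annotation


def true_marker_genes(config: SynthConfig, subgroup: str) -> list[str]:
    """Ground-truth marker block for one subgroup (for recall checks)."""
    _, layout = gen_gene_annotation(config)
    return list(layout["marker_blocks"][subgroup])


# ---------------------------------------------------------------------------
# Bulk generator
# ---------------------------------------------------------------------------


def gen_bulk_cohort(config: SynthConfig, signature: GeneSignature) -> BulkCohort:
    """Generate a pooled bulk cohort with planted response signal.

    Log-scale expression ~ N(0,1) per gene; NPD samples get a
    +bulk_effect shift on signature genes, then batch offset/scale are
    applied; survival is exponential per response class with uniform
    censoring at the configured rate.
    """
    rngs = _streams(config.seed, ["means", "labels", "counts", "bulk", "survival"])
    rng = rngs["bulk"]
    rng_surv = rngs["survival"]
    n = config.bulk_n_samples
    genes = [f"G{i + 1:05d}" for i in range(config.bulk_n_genes)]
    missing = set(signature.genes) - set(genes)
    if missing:
        raise ConfigError(
            f"signature genes outside the bulk gene universe: {sorted(missing)[:5]}"
        )

    samples = [f"S{i + 1:04d}" for i in range(n)]
    n_npd = int(round(config.bulk_npd_fraction * n))
    response = np.array(["NPD"] * n_npd + ["PD"] * (n - n_npd))
    rng.shuffle(response)

    expr = rng.normal(0.0, 1.0, size=(n, len(genes)))
    sig_idx = [genes.index(g) for g in signature.genes]
    expr[np.ix_(response == "NPD", sig_idx)] += config.bulk_effect

    batches = list(config.batch_shifts)
    batch = np.array([batches[i % len(batches)] for i in range(n)])
    rng.shuffle(batch)
    for name, (offset, scale) in config.batch_shifts.items():
        mask = batch == name
        expr[mask] = expr[mask] * scale + offset

    rates = np.array([config.survival_model[r] for r in response])
    times = rng_surv.exponential(1.0 / rates)
    events = np.ones(n, dtype=int)
    censor = rng_surv.random(n) < config.censoring_rate
    times = np.where(censor, times * rng_surv.random(n), times)
    events[censor] = 0

    expression = pd.DataFrame(expr, index=samples, columns=genes)
    clinical = pd.DataFrame(
        {
            "sample_id": samples,
            "response": response,
            "batch": batch,
            "os_time": times,
            "os_event": events,
        },
        index=samples,
    )
    return BulkCohort(expression=expression, clinical=clinical)
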