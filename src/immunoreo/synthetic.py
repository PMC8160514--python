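"""Synthetic reference cohorts, single-cell matrices and bulk mixtures.

The generator emulates the data layout the estimator consumes: marker-
structured expression profiles for a panel of immune cell types, a cancer
reference and a normal-tissue control, all sharing a log-normal baseline;
a labeled single-cell-like matrix drawn from the same profiles; and
pseudo-bulk mixtures of known composition built by sampling and summing
single cells.

The expression model is multiplicative: gene g has baseline
``exp(Normal(baseline_log_mean, baseline_log_sd))`` shared by every
cohort; each cell type's designated marker genes are multiplied by
``marker_fold`` in that type only; every sample (or cell) adds independent
log-normal noise ``exp(Normal(0, noise_sd))`` per gene.  Only within-
sample ranks reach the scoring core, so the distributional family mainly
matters for calibration realism.

Bulk mixtures follow the infiltration scenario of interest: per sample a
cancer fraction f is drawn uniformly from [0.5, 0.99], the remainder
1 - f is split across immune types by a uniform simplex draw, fractions
become integer cell counts by largest-remainder rounding, and cells are
drawn from the single-cell pool (with replacement when a pool is smaller
than its demand).  All randomness flows from explicit seeds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_CELL_TYPES",
    "SyntheticConfig",
    "BulkSimConfig",
    "make_reference_cohorts",
    "make_single_cell_matrix",
    "simulate_bulk",
    "largest_remainder_counts",
]

# Eight immune cell types commonly profiled in tumor microenvironment work.
DEFAULT_CELL_TYPES = (
    "B_cells",
    "CD4_T_cells",
    "CD8_T_cells",
    "NK_cells",
    "macrophages",
    "monocytes",
    "dendritic_cells",
    "neutrophils",
)

CANCER_LABEL = "cancer"
CONTROL_LABEL = "control"


@dataclass(frozen=True)
class SyntheticConfig:
    """Shape and effect-size parameters of the synthetic expression model."""

    seed: int
    n_genes: int = 2000
    cell_types: tuple[str, ...] = DEFAULT_CELL_TYPES
    markers_per_type: int = 40
    marker_fold: float = 6.0
    baseline_log_mean: float = 2.0
    baseline_log_sd: float = 1.0
    noise_sd: float = 0.2
    samples_per_reference: int = 30

    def __post_init__(self):
        if self.markers_per_type * len(self.cell_types) > self.n_genes:
            raise ValueError("markers_per_type * n_cell_types exceeds n_genes")
        if self.marker_fold <= 1:
            raise ValueError("marker_fold must exceed 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if CANCER_LABEL in self.cell_types or CONTROL_LABEL in self.cell_types:
            raise ValueError("cell type names 'cancer'/'control' are reserved")


@dataclass(frozen=True)
class BulkSimConfig:
    """Composition parameters of the simulated bulk cohort."""

    seed: int
    n_samples: int = 100
    cells_per_sample: int = 1000
    cancer_fraction_range: tuple[float, float] = (0.5, 0.99)

    def __post_init__(self):
        low, high = self.cancer_fraction_range
        if not 0 < low <= high < 1:
            raise ValueError("cancer_fraction_range must satisfy 0 < low <= high < 1")
        if self.cells_per_sample < 1:
            raise ValueError("cells_per_sample must be >= 1")


def _gene_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"G{i:0{width}d}" for i in range(1, n + 1)]


def _model(cfg: SyntheticConfig):
    """Baseline vector, per-population mean profiles and the marker map.

    Deterministic given cfg.seed; the sampling of individual profiles uses
    separate streams so cohort and single-cell draws stay reproducible
    independently of each other.
    """
    rng = np.random.default_rng(cfg.seed)
    genes = _gene_ids(cfg.n_genes)
    baseline = np.exp(rng.normal(cfg.baseline_log_mean, cfg.baseline_log_sd, cfg.n_genes))
    marker_pool = rng.choice(
        cfg.n_genes, size=cfg.markers_per_type * len(cfg.cell_types), replace=False
    )
    markers: dict[str, list[str]] = {}
    means: dict[str, np.ndarray] = {
        CANCER_LABEL: baseline.copy(),
        CONTROL_LABEL: baseline.copy(),
    }
    for t, ct in enumerate(cfg.cell_types):
        idx = marker_pool[t * cfg.markers_per_type : (t + 1) * cfg.markers_per_type]
        markers[ct] = sorted(genes[i] for i in idx)
        mean = baseline.copy()
        mean[idx] *= cfg.marker_fold
        means[ct] = mean
    return genes, means, markers


def _draw_samples(
    mean: np.ndarray, n: int, noise_sd: float, rng: np.random.Generator
) -> np.ndarray:
    if noise_sd <= 0:
        return np.repeat(mean[:, None], n, axis=1)
    noise = rng.normal(0.0, noise_sd, size=(len(mean), n))
    return mean[:, None] * np.exp(noise)


def make_reference_cohorts(
    cfg: SyntheticConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, pd.DataFrame], dict[str, list[str]]]:
    """Generate (cancer, control, per-type immune cohorts, truth catalog).

    Each cohort has ``samples_per_reference`` columns drawn around its
    population mean profile with multiplicative log-normal noise.  The
    truth catalog records the planted marker genes per cell type (the
    candidate list a marker-gene compendium would supply).
    """
    genes, means, markers = _model(cfg)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    n = cfg.samples_per_reference

    def cohort(name: str) -> pd.DataFrame:
        data = _draw_samples(means[name], n, cfg.noise_sd, rng)
        cols = [f"{name}_s{j:02d}" for j in range(1, n + 1)]
        return pd.DataFrame(data, index=genes, columns=cols)

    cancer = cohort(CANCER_LABEL)
    control = cohort(CONTROL_LABEL)
    immune = {ct: cohort(ct) for ct in cfg.cell_types}
    return cancer, control, immune, markers


def make_single_cell_matrix(
    cfg: SyntheticConfig, cells_per_type: int, n_donors: int = 1
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a labeled single-cell-like matrix (cancer + immune types).

    Each cell is an independent draw from its population's profile with
    the configured noise.  Donors are assigned round-robin.  Returns
    ``(matrix over barcodes, labels)`` with label columns
    (barcode_id, cell_type, donor_id).
    """
    if cells_per_type < 1:
        raise ValueError("cells_per_type must be >= 1")
    genes, means, _ = _model(cfg)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2]))
    populations = [CANCER_LABEL, *cfg.cell_types]
    blocks, barcodes, rows = [], [], []
    for pop in populations:
        blocks.append(_draw_samples(means[pop], cells_per_type, cfg.noise_sd, rng))
        for j in range(cells_per_type):
            bc = f"{pop}_c{j + 1:04d}"
            barcodes.append(bc)
            rows.append((bc, pop, f"D{(len(rows) % n_donors) + 1}"))
    matrix = pd.DataFrame(np.hstack(blocks), index=genes, columns=barcodes)
    labels = pd.DataFrame(rows, columns=["barcode_id", "cell_type", "donor_id"])
    return matrix, labels


def largest_remainder_counts(weights: np.ndarray, total: int) -> np.ndarray:
    """Integer apportionment of `total` by largest remainder.

    Floors total*weights, then hands the leftover units to the largest
    fractional parts (ties broken by position).  The result always sums to
    `total`.
    """
    weights = np.asarray(weights, dtype=float)
    if weights.sum() <= 0:
        raise ValueError("weights must have positive sum")
    quota = weights / weights.sum() * total
    counts = np.floor(quota).astype(np.int64)
    short = total - int(counts.sum())
    if short > 0:
        order = np.argsort(-(quota - counts), kind="stable")
        counts[order[:short]] += 1
    return counts


def simulate_bulk(
    cells: pd.DataFrame, labels: pd.DataFrame, cfg: BulkSimConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Build bulk mixtures of known composition from a single-cell pool.

    Per sample: cancer fraction f ~ Uniform(cancer_fraction_range); the
    remaining 1 - f is split across immune types by a symmetric Dirichlet
    (uniform simplex) draw; fractions are converted to integer cell counts
    by largest-remainder rounding; the required number of cells per type
    is drawn from that type's pool (with replacement when the pool is
    smaller than the demand) and the bulk column is the sum of the drawn
    cell columns.  The returned fraction table records realized counts /
    cells_per_sample, so its fractions sum to exactly 1 per sample.
    """
    labels = labels.set_index("barcode_id") if "barcode_id" in labels.columns else labels
    by_type = {
        ct: np.array([cells.columns.get_loc(b) for b in grp.index])
        for ct, grp in labels.groupby("cell_type")
    }
    if CANCER_LABEL not in by_type:
        raise ValueError(f"labels must include a {CANCER_LABEL!r} cell type")
    immune_types = sorted(t for t in by_type if t != CANCER_LABEL)
    rng = np.random.default_rng(cfg.seed)
    values = cells.to_numpy(dtype=float)
    low, high = cfg.cancer_fraction_range
    bulk_cols, frac_rows = [], []
    sample_ids = [f"bulk_s{j:03d}" for j in range(1, cfg.n_samples + 1)]
    for sid in sample_ids:
        f = rng.uniform(low, high)
        simplex = rng.dirichlet(np.ones(len(immune_types)))
        weights = np.concatenate([[f], (1.0 - f) * simplex])
        counts = largest_remainder_counts(weights, cfg.cells_per_sample)
        column = np.zeros(values.shape[0])
        for ct, n_cells in zip([CANCER_LABEL, *immune_types], counts):
            if n_cells == 0:
                frac_rows.append((sid, ct, 0.0))
                continue
            pool = by_type[ct]
            chosen = rng.choice(pool, size=n_cells, replace=n_cells > len(pool))
            column += values[:, chosen].sum(axis=1)
            frac_rows.append((sid, ct, n_cells / cfg.cells_per_sample))
        bulk_cols.append(column)
    bulk = pd.DataFrame(np.column_stack(bulk_cols), index=cells.index, columns=sample_ids)
    fractions = pd.DataFrame(frac_rows, columns=["sample_id", "cell_type", "fraction"])
    return bulk, fractions
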