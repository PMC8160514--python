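"""End-to-end convenience wrappers tying the pipeline stages together.

The full estimator runs in three steps: (1) derive cancer-specific
signature genes per immune cell type against the cancer stable-pair
background; (2) calibrate the score-to-proportion transform on in-silico
spike-in mixtures; (3) score query samples and apply the transforms.
These wrappers exist so callers (including the CLI and the synthetic
benchmark) do not have to wire the modules by hand.
"""

from __future__ import annotations

import logging

import pandas as pd

from .calibration import TransformParams, build_grid, estimate_proportions, fit_power_transform
from .pairs import StablePairSet, find_stable_pairs
from .signatures import BinomialTestConfig, SignatureSet, build_signatures, call_updegs

logger = logging.getLogger(__name__)

__all__ = ["derive_signatures", "calibrate", "estimate"]


def derive_signatures(
    cancer: pd.DataFrame,
    immune_cohorts: dict[str, pd.DataFrame],
    catalog: dict[str, list[str]],
    *,
    pair_threshold: float = 0.99,
    individual_fdr: float = 0.05,
    cfg: BinomialTestConfig | None = None,
) -> tuple[StablePairSet, SignatureSet]:
    """Step 1: stable pairs from the cancer reference, then signatures.

    All candidate genes across cell types become the focus set of the
    stable-pair search; each immune cohort's samples are tested for
    individual up-DEGs against that background; the binomial population
    test and the uniqueness filter produce the final signatures.
    """
    all_candidates = sorted({g for genes in catalog.values() for g in genes})
    background = find_stable_pairs(cancer, all_candidates, threshold=pair_threshold)
    per_cell_flags = {}
    for ct, genes in catalog.items():
        cohort = immune_cohorts[ct]
        flags, _ = call_updegs(cohort, genes, background, individual_fdr)
        per_cell_flags[ct] = flags
        logger.info("%s: %d/%d candidates up in >=1 sample",
                    ct, int(flags.any(axis=1).sum()), len(flags))
    signatures = build_signatures(catalog, per_cell_flags, cfg)
    return background, signatures


def calibrate(
    cancer: pd.DataFrame,
    control: pd.DataFrame,
    immune_cohorts: dict[str, pd.DataFrame],
    signatures: SignatureSet,
    background: StablePairSet,
    *,
    fractions=None,
    harmonize: bool = True,
) -> dict[str, TransformParams]:
    """Step 2: spike-in grids and fitted power transforms per cell type."""
    grids = build_grid(
        cancer, control, immune_cohorts, signatures, background,
        fractions, harmonize=harmonize,
    )
    return {ct: fit_power_transform(grid) for ct, grid in grids.items()}


def estimate(
    matrix: pd.DataFrame,
    signatures: SignatureSet,
    background: StablePairSet,
    params: dict[str, TransformParams],
) -> pd.DataFrame:
    """Step 3: per-sample, per-cell-type estimated proportions."""
    return estimate_proportions(matrix, signatures, background, params)
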