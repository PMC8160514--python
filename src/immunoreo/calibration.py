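"""Spike-in mixture calibration: from UpScores to estimated proportions.

UpScores of different cell types live on different scales (they depend on
signature size and background pair counts), so raw scores are comparable
across samples but not across cell types.  Calibration fixes this with an
in-silico spike-in series per cell type: mixtures of 60% cancer median
profile, X% immune median and (40 - X)% normal-tissue ("control") median,
with X running from 0.8% to 25.6% in 0.8% steps.  The grid's UpScores S
are shifted by their minimum and a power law

    F = V1 * (S - S_min)^V2

is fitted with the known spike-in fractions F as the response.  Applying
the fitted transform to a query sample's UpScore yields an estimated
proportion on a common scale.  Estimates are deliberately NOT renormalized
to sum to one across cell types.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .io import validate_matrix
from .pairs import StablePairSet
from .scoring import count_orderings, score_cohort, upscore
from .signatures import SignatureSet

logger = logging.getLogger(__name__)

__all__ = [
    "CalibrationError",
    "MixtureGrid",
    "TransformParams",
    "default_fraction_grid",
    "harmonize_cohorts",
    "median_profile",
    "mix_profiles",
    "build_grid",
    "fit_power_transform",
    "apply_transform",
    "estimate_proportions",
    "write_params",
    "read_params",
]


class CalibrationError(RuntimeError):
    """Raised when a mixture grid cannot support a power-law fit."""


def default_fraction_grid() -> np.ndarray:
    """The spike-in fractions: 0.008 to 0.256 inclusive, step 0.008 (32 points).

    The range targets cell types that occupy small fractions of the tumor
    microenvironment.
    """
    return np.round(np.arange(1, 33) * 0.008, 10)


@dataclass
class MixtureGrid:
    """Spike-in fractions and the UpScores they produced for one cell type."""

    cell_type: str
    fractions: np.ndarray
    upscores: np.ndarray

    def __post_init__(self):
        self.fractions = np.asarray(self.fractions, dtype=float)
        self.upscores = np.asarray(self.upscores, dtype=float)
        if len(self.fractions) != len(self.upscores):
            raise ValueError("fractions and upscores must have equal length")
        if np.any(np.diff(self.fractions) <= 0):
            raise ValueError("fractions must be strictly increasing")
        if np.any(self.fractions <= 0) or np.any(self.fractions > 0.40):
            raise ValueError("fractions must lie in (0, 0.40]")


@dataclass
class TransformParams:
    """Fitted power-law parameters for one cell type.

    ``apply`` maps an UpScore S to V1 * max(S - S_min, 0)^V2; scores at or
    below S_min map to exactly 0.
    """

    cell_type: str
    V1: float
    V2: float
    S_min: float
    fit_rmse: float = float("nan")
    grid: MixtureGrid | None = field(default=None, repr=False)

    def __post_init__(self):
        if self.V1 <= 0 or self.V2 <= 0:
            raise ValueError("V1 and V2 must be positive")


def median_profile(cohort: pd.DataFrame) -> pd.Series:
    """Per-gene median expression across a cohort's samples."""
    return cohort.median(axis=1)


def harmonize_cohorts(cohorts: dict[str, pd.DataFrame]) -> dict[str, pd.DataFrame]:
    """Rescale cohorts so their global median expression levels agree.

    Mixing operates on the linear scale, so gross platform-scale
    differences between reference cohorts would distort the effective
    spike-in fraction.  Each cohort is multiplied by a single constant
    bringing its global (all-values) median to the median of the cohorts'
    global medians.  Rank structure within every sample is untouched.
    Externally harmonized matrices can be passed straight through by
    skipping this step.
    """
    medians = {name: float(np.median(df.to_numpy())) for name, df in cohorts.items()}
    if any(m <= 0 for m in medians.values()):
        raise ValueError("cohort global medians must be positive for rescaling")
    target = float(np.median(list(medians.values())))
    return {name: df * (target / medians[name]) for name, df in cohorts.items()}


def mix_profiles(
    cancer_median: pd.Series,
    immune_median: pd.Series,
    control_median: pd.Series,
    x: float,
) -> pd.Series:
    """In-silico mixture: 60% cancer + x immune + (40% - x) control, gene-wise."""
    if not 0.0 <= x <= 0.40:
        raise ValueError("immune fraction x must lie in [0, 0.40]")
    if not (cancer_median.index.equals(immune_median.index) and
            cancer_median.index.equals(control_median.index)):
        raise ValueError("profiles must share an identical gene index")
    return 0.60 * cancer_median + x * immune_median + (0.40 - x) * control_median


def build_grid(
    cancer: pd.DataFrame,
    control: pd.DataFrame,
    immune_cohorts: dict[str, pd.DataFrame],
    signatures: SignatureSet,
    background: StablePairSet,
    fractions: np.ndarray | None = None,
    *,
    harmonize: bool = True,
) -> dict[str, MixtureGrid]:
    """Score the spike-in series for every cell type with a signature.

    Reference cohorts are reduced to median profiles (after optional
    scale harmonization); each grid point is the UpScore of the mixture at
    that immune fraction, deterministic given the inputs.
    """
    fractions = default_fraction_grid() if fractions is None else np.asarray(fractions, float)
    shared = cancer.index.intersection(control.index)
    for df in immune_cohorts.values():
        shared = shared.intersection(df.index)
    if len(shared) == 0:
        raise ValueError("reference cohorts share no genes")
    cohorts = {"cancer": cancer.loc[shared], "control": control.loc[shared]}
    cohorts.update({ct: df.loc[shared] for ct, df in immune_cohorts.items()})
    if harmonize:
        cohorts = harmonize_cohorts(cohorts)
    cancer_med = median_profile(cohorts["cancer"])
    control_med = median_profile(cohorts["control"])
    grids: dict[str, MixtureGrid] = {}
    for ct in signatures.nonempty_types():
        if ct not in immune_cohorts:
            raise ValueError(f"no reference cohort for cell type {ct!r}")
        immune_med = median_profile(cohorts[ct])
        scores = []
        for x in fractions:
            mixture = mix_profiles(cancer_med, immune_med, control_med, float(x))
            s, _ = upscore(count_orderings(mixture, signatures.entries[ct], background))
            scores.append(s)
        grids[ct] = MixtureGrid(cell_type=ct, fractions=fractions, upscores=np.array(scores))
    return grids


def fit_power_transform(grid: MixtureGrid) -> TransformParams:
    """Least-squares fit of F = V1 * (S - S_min)^V2 over the mixture grid.

    S_min is the grid's minimal UpScore (by construction the lowest
    spike-in, which barely produces reversal significance).  Points with
    S - S_min = 0 anchor the shift but carry no shape information
    (0^V2 = 0 for any V2 > 0) and are excluded from the fit.  The fit is
    ordinary least squares in linear space, initialized from the OLS line
    of log F on log(S - S_min); a log-space-only fit is available by using
    those initial values directly.
    """
    s = np.asarray(grid.upscores, dtype=float)
    f = np.asarray(grid.fractions, dtype=float)
    if len(s) < 4:
        raise CalibrationError("need at least 4 grid points")
    s_min = float(np.min(s))
    shifted = s - s_min
    usable = shifted > 0
    if np.allclose(s, s[0]) or usable.sum() < 4:
        raise CalibrationError(
            f"{grid.cell_type}: grid has no dynamic range "
            f"({int(usable.sum())} usable points)"
        )
    ls, lf = np.log(shifted[usable]), np.log(f[usable])
    v2_0, logv1_0 = np.polyfit(ls, lf, 1)
    v2_0 = max(v2_0, 1e-6)
    try:
        popt, _ = curve_fit(
            lambda t, v1, v2: v1 * np.power(t, v2),
            shifted[usable],
            f[usable],
            p0=[float(np.exp(logv1_0)), float(v2_0)],
            bounds=([1e-12, 1e-6], [np.inf, np.inf]),
            maxfev=10000,
        )
    except RuntimeError as exc:  # pragma: no cover - pathological grids
        raise CalibrationError(f"{grid.cell_type}: power fit failed: {exc}") from exc
    v1, v2 = map(float, popt)
    resid = f[usable] - v1 * shifted[usable] ** v2
    rmse = float(np.sqrt(np.mean(resid**2)))
    return TransformParams(
        cell_type=grid.cell_type, V1=v1, V2=v2, S_min=s_min, fit_rmse=rmse, grid=grid
    )


def apply_transform(upscore_value: float, params: TransformParams) -> float:
    """Estimated proportion for one UpScore: V1 * max(S - S_min, 0)^V2."""
    shifted = upscore_value - params.S_min
    if shifted <= 0:
        if shifted < 0:
            logger.debug(
                "%s: upscore %.3f below calibration range (S_min=%.3f), clamped to 0",
                params.cell_type, upscore_value, params.S_min,
            )
        return 0.0
    return params.V1 * shifted**params.V2


def estimate_proportions(
    matrix: pd.DataFrame,
    signatures: SignatureSet,
    background: StablePairSet,
    params: dict[str, TransformParams],
) -> pd.DataFrame:
    """Score a query cohort and transform UpScores to proportions.

    Returns a tidy DataFrame (sample_id, cell_type, upscore,
    estimated_proportion, flag).  Estimates above the calibrated range
    (the grid's top spike-in fraction) are extrapolations and flagged
    ``above_calibration_range``; UpScores below S_min clamp to 0 with flag
    ``below_calibration_range``.  Estimates are comparable across cell
    types and samples but are not constrained to sum to 1.
    """
    matrix = validate_matrix(matrix)
    missing = [ct for ct in signatures.nonempty_types() if ct not in params]
    if missing:
        raise ValueError(f"missing transform parameters for cell types: {missing}")
    scored = score_cohort(matrix, signatures, background)
    out_rows = []
    for row in scored.itertuples(index=False):
        prm = params[row.cell_type]
        if np.isnan(row.upscore):
            out_rows.append((row.sample_id, row.cell_type, np.nan, np.nan, "unscored"))
            continue
        est = apply_transform(row.upscore, prm)
        flag = ""
        if row.upscore < prm.S_min:
            flag = "below_calibration_range"
        elif prm.grid is not None and est > float(prm.grid.fractions[-1]):
            flag = "above_calibration_range"
        out_rows.append((row.sample_id, row.cell_type, row.upscore, est, flag))
    return pd.DataFrame(
        out_rows,
        columns=["sample_id", "cell_type", "upscore", "estimated_proportion", "flag"],
    )


def write_params(params: dict[str, TransformParams], path) -> None:
    """Serialize fitted transforms (with grid provenance) as JSON."""
    payload = {}
    for ct, prm in params.items():
        rec = {"V1": prm.V1, "V2": prm.V2, "S_min": prm.S_min, "fit_rmse": prm.fit_rmse}
        if prm.grid is not None:
            rec["grid"] = {
                "fractions": prm.grid.fractions.tolist(),
                "upscores": prm.grid.upscores.tolist(),
            }
        payload[ct] = rec
    Path(path).write_text(json.dumps(payload, indent=2))


def read_params(path) -> dict[str, TransformParams]:
    payload = json.loads(Path(path).read_text())
    params = {}
    for ct, rec in payload.items():
        grid = None
        if "grid" in rec:
            grid = MixtureGrid(
                cell_type=ct,
                fractions=np.asarray(rec["grid"]["fractions"]),
                upscores=np.asarray(rec["grid"]["upscores"]),
            )
        params[ct] = TransformParams(
            cell_type=ct, V1=rec["V1"], V2=rec["V2"], S_min=rec["S_min"],
            fit_rmse=rec.get("fit_rmse", float("nan")), grid=grid,
        )
    return params
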