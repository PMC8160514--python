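"""Per-sample, per-cell-type upregulated scores (UpScores).

For one cell type with signature genes {G_sig.1 .. G_sig.m}: every stable
background pair joining a signature gene to a partner gene contributes to
the background counts a (signature gene above partner) and b (below);
evaluating the same pairs in a query sample gives c and d.  More
infiltration of the cell type pushes signature genes up the within-sample
ranking, inflating c at the expense of d; the one-sided Fisher exact
p-value of [[c, d], [a, b]] measures that reversal, and the UpScore is
its -log10.  Only within-sample orderings enter, so the score is invariant
to any monotone per-sample normalization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._stats import P_FLOOR, fisher_greater_p
from .pairs import StablePairSet
from .signatures import SignatureSet

logger = logging.getLogger(__name__)

__all__ = ["ContingencyCounts", "count_orderings", "upscore", "score_cohort"]


@dataclass(frozen=True)
class ContingencyCounts:
    """Pooled ordering counts for one (sample, cell type) pair.

    a/b: background pairs with the signature gene above/below its partner;
    c/d: the same pairs evaluated in the query sample (strict inequalities;
    ties count toward neither, so c + d <= a + b).
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")
        if self.a + self.b < 1:
            raise ValueError("no background pairs: a + b must be >= 1")


def _signature_pairs(
    signature: list[str], background: StablePairSet, gene_pos: dict[str, int]
):
    """Index arrays (sig_idx, partner_idx, sig_is_greater) over all
    background pairs touching a signature gene whose partner is present in
    the query matrix.  A pair between two signature genes contributes once
    per signature endpoint (direction taken relative to that endpoint),
    mirroring the per-gene pooling."""
    si, pi, up = [], [], []
    for g in signature:
        gi = gene_pos.get(g)
        if gi is None:
            continue
        below, above = background.partners(g)
        for h in below:
            hj = gene_pos.get(h)
            if hj is not None:
                si.append(gi); pi.append(hj); up.append(True)
        for h in above:
            hj = gene_pos.get(h)
            if hj is not None:
                si.append(gi); pi.append(hj); up.append(False)
    return (
        np.asarray(si, dtype=np.int64),
        np.asarray(pi, dtype=np.int64),
        np.asarray(up, dtype=bool),
    )


def count_orderings(
    sample: pd.Series, signature: list[str], background: StablePairSet
) -> ContingencyCounts:
    """Pooled ordering counts for one expression column and one signature."""
    gene_pos = {g: i for i, g in enumerate(sample.index)}
    si, pi, up = _signature_pairs(list(signature), background, gene_pos)
    if len(si) == 0:
        raise ValueError("no background pairs involve any signature gene")
    a = int(up.sum())
    b = int(len(up) - a)
    col = sample.to_numpy(dtype=float)
    c = int((col[si] > col[pi]).sum())
    d = int((col[si] < col[pi]).sum())
    return ContingencyCounts(a=a, b=b, c=c, d=d)


def upscore(counts: ContingencyCounts, alternative: str = "greater") -> tuple[float, float]:
    """UpScore and raw Fisher p for pooled ordering counts.

    The default (and the method's defined score) is one-sided: enrichment
    of the sample for signature-above-partner orderings relative to the
    background.  ``alternative="two-sided"`` is available for sensitivity
    analysis only.  The p-value is floored at 1e-300 before the log so the
    score stays finite.

    Returns ``(upscore, raw_p)`` with ``upscore = -log10(raw_p)``.
    """
    if alternative == "greater":
        raw_p = fisher_greater_p(counts.c, counts.d, counts.a, counts.b)
    elif alternative == "two-sided":
        from scipy.stats import fisher_exact

        raw_p = float(
            fisher_exact(
                [[counts.c, counts.d], [counts.a, counts.b]], alternative="two-sided"
            ).pvalue
        )
    else:
        raise ValueError(f"unknown alternative: {alternative!r}")
    raw_p = max(float(raw_p), P_FLOOR)
    return -float(np.log10(raw_p)), raw_p


def score_cohort(
    matrix: pd.DataFrame,
    signatures: SignatureSet,
    background: StablePairSet,
) -> pd.DataFrame:
    """UpScores for every (sample, non-empty cell type) of a cohort.

    Returns a tidy DataFrame with columns (sample_id, cell_type, upscore,
    raw_p, a, b, c, d).  Cell types whose signature has no usable
    background pairs are recorded with missing score and a warning rather
    than a hard failure.
    """
    if matrix.shape[0] == 0 or matrix.shape[1] == 0:
        raise ValueError("empty expression matrix")
    types = signatures.nonempty_types()
    if not types:
        raise ValueError("all signatures are empty")
    gene_pos = {g: i for i, g in enumerate(matrix.index)}
    values = matrix.to_numpy(dtype=float)
    rows = []
    for ct in types:
        si, pi, up = _signature_pairs(signatures.entries[ct], background, gene_pos)
        if len(si) == 0:
            logger.warning("cell type %s: no background pairs in query; skipped", ct)
            for s in matrix.columns:
                rows.append((s, ct, np.nan, np.nan, 0, 0, 0, 0))
            continue
        a = int(up.sum())
        b = int(len(up) - a)
        above = values[si, :] > values[pi, :]  # (pairs, samples)
        below = values[si, :] < values[pi, :]
        c = above.sum(axis=0).astype(np.int64)
        d = below.sum(axis=0).astype(np.int64)
        p = fisher_greater_p(c, d, np.full_like(c, a), np.full_like(c, b))
        p = np.clip(np.atleast_1d(p), P_FLOOR, 1.0)
        scores = -np.log10(p)
        for j, s in enumerate(matrix.columns):
            rows.append((s, ct, float(scores[j]), float(p[j]), a, b, int(c[j]), int(d[j])))
    return pd.DataFrame(
        rows, columns=["sample_id", "cell_type", "upscore", "raw_p", "a", "b", "c", "d"]
    )
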