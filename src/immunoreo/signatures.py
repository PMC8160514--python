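"""Cancer-specific signature genes per immune cell type.

The derivation has three stages.  (1) For every profiled immune-cell
sample, each candidate marker gene is tested for *individual-level
upregulation*: the gene's orderings against its stable-pair partners in
the sample are compared with the cancer-reference background by a
one-sided Fisher exact test, and calls are made at a per-sample BH FDR.
(2) A cumulative binomial test asks whether a non-random proportion of a
cell type's samples carried the up call; the upper-tail p-value
``P(X >= k)`` with null success probability P0 (default 0.5) is BH-adjusted
within the cell type.  (3) Genes retained for two or more cell types are
removed, leaving pairwise-disjoint signatures.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import binom

from ._stats import bh_adjust, fisher_greater_p
from .pairs import StablePairSet

logger = logging.getLogger(__name__)

__all__ = [
    "BinomialTestConfig",
    "SignatureSet",
    "rankcomp_updeg",
    "call_updegs",
    "binomial_population_p",
    "build_signatures",
]


@dataclass(frozen=True)
class BinomialTestConfig:
    """Population-level test configuration.

    P0 is the null probability of a gene being called up in one sample by
    chance; population_fdr the BH threshold on the adjusted binomial tail.
    """

    P0: float = 0.5
    population_fdr: float = 0.05

    def __post_init__(self):
        if not 0.0 < self.P0 < 1.0:
            raise ValueError("P0 must lie in (0, 1)")


@dataclass
class SignatureSet:
    """Per-cell-type signature gene lists with population-level provenance.

    ``entries`` maps cell_type -> ordered gene list; lists are pairwise
    disjoint across cell types.  ``provenance`` carries, per cell type, the
    adjusted population p-value of every retained gene.
    """

    entries: dict[str, list[str]]
    provenance: dict[str, dict[str, float]] = field(default_factory=dict)

    def __post_init__(self):
        seen: dict[str, str] = {}
        for ct, genes in self.entries.items():
            for g in genes:
                if g in seen:
                    raise ValueError(
                        f"gene {g!r} assigned to both {seen[g]!r} and {ct!r}"
                    )
                seen[g] = ct

    def nonempty_types(self) -> list[str]:
        return [ct for ct, genes in self.entries.items() if genes]

    def to_json(self, path) -> None:
        payload = {
            ct: {
                "genes": genes,
                "adjusted_p": {g: self.provenance.get(ct, {}).get(g) for g in genes},
            }
            for ct, genes in self.entries.items()
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    def to_tsv(self, path) -> None:
        rows = [
            (ct, g, self.provenance.get(ct, {}).get(g, float("nan")))
            for ct, genes in self.entries.items()
            for g in genes
        ]
        pd.DataFrame(rows, columns=["cell_type", "gene_id", "adjusted_p"]).to_csv(
            path, sep="\t", index=False
        )

    @classmethod
    def from_json(cls, path) -> "SignatureSet":
        payload = json.loads(Path(path).read_text())
        entries = {ct: rec["genes"] for ct, rec in payload.items()}
        prov = {ct: rec.get("adjusted_p", {}) for ct, rec in payload.items()}
        return cls(entries=entries, provenance=prov)


def _pair_index(
    candidates: list[str], background: StablePairSet, gene_pos: dict[str, int]
):
    """Flatten background partner lists into index arrays for fast counting.

    Returns (pair_cand, pair_self, pair_partner, dir_gt, n_gt, n_lt) where
    pair_* and dir_gt are parallel arrays over all (candidate, partner)
    pairs whose partner is present in the expression matrix (dir_gt: the
    background places the candidate above the partner); n_gt/n_lt count,
    per candidate, background pairs with the candidate above/below.
    """
    pc, ps, pp = [], [], []
    dir_gt = []
    n_gt = np.zeros(len(candidates), dtype=np.int64)
    n_lt = np.zeros(len(candidates), dtype=np.int64)
    for i, g in enumerate(candidates):
        gi = gene_pos.get(g)
        if gi is None:
            continue
        below, above = background.partners(g)
        for h in below:
            hj = gene_pos.get(h)
            if hj is None:
                continue
            pc.append(i); ps.append(gi); pp.append(hj); dir_gt.append(True)
            n_gt[i] += 1
        for h in above:
            hj = gene_pos.get(h)
            if hj is None:
                continue
            pc.append(i); ps.append(gi); pp.append(hj); dir_gt.append(False)
            n_lt[i] += 1
    return (
        np.asarray(pc, dtype=np.int64),
        np.asarray(ps, dtype=np.int64),
        np.asarray(pp, dtype=np.int64),
        np.asarray(dir_gt, dtype=bool),
        n_gt,
        n_lt,
    )


def call_updegs(
    cohort: pd.DataFrame,
    candidates,
    background: StablePairSet,
    individual_fdr: float = 0.05,
    *,
    max_rounds: int = 1,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Individual-level up-DEG calls for every sample of a cohort.

    For candidate gene g in one sample: with n_gt/n_lt the counts of
    background pairs placing g above/below its partners, and c_gt/c_lt the
    counts of the same pairs showing g above/below the partner in the
    sample (strict inequalities; ties count toward neither), the one-sided
    Fisher exact p of [[c_gt, c_lt], [n_gt, n_lt]] is BH-adjusted across
    candidates within the sample.  A gene is flagged up iff the adjusted p
    falls below ``individual_fdr`` AND the sample's fraction of
    g-above-partner orderings exceeds the background's (upregulation is
    directional; the 2x2 test alone is not).

    ``max_rounds > 1`` enables the iterative refinement: partner genes
    flagged up in the previous round are excluded from both the background
    and sample counts (their orderings are no longer null evidence) and
    the sample is re-tested, stopping at a fixed point or after
    ``max_rounds`` rounds.  The one-pass default is the reproducible core.

    Candidates with zero background pairs carry p = 1 and are never up.

    Returns ``(flags, adjusted_p)``: candidate-by-sample DataFrames of
    bool and float.
    """
    candidates = [g for g in dict.fromkeys(candidates)]
    if not candidates:
        raise ValueError("no candidate genes supplied")
    if max_rounds < 1:
        raise ValueError("max_rounds must be >= 1")
    gene_pos = {g: i for i, g in enumerate(cohort.index)}
    pc, ps, pp, dir_gt, n_gt0, n_lt0 = _pair_index(candidates, background, gene_pos)
    if ((n_gt0 + n_lt0) == 0).any():
        logger.warning(
            "%d candidates have no background pairs and are never called up",
            int(((n_gt0 + n_lt0) == 0).sum()),
        )
    # candidate index of every partner gene, or -1 (non-candidate partners
    # are never excluded by the iterative refinement)
    cand_pos = {gene_pos[g]: i for i, g in enumerate(candidates) if g in gene_pos}
    partner_cand = np.array([cand_pos.get(int(j), -1) for j in pp], dtype=np.int64)

    values = cohort.to_numpy(dtype=float)
    n_cand = len(candidates)
    flags = np.zeros((n_cand, cohort.shape[1]), dtype=bool)
    adj = np.ones((n_cand, cohort.shape[1]), dtype=float)
    for s in range(cohort.shape[1]):
        col = values[:, s]
        up_now = np.zeros(n_cand, dtype=bool)
        for _ in range(max_rounds):
            if len(pc):
                keep = (partner_cand < 0) | ~up_now[partner_cand]
                kpc = pc[keep]
                n_gt = np.bincount(kpc[dir_gt[keep]], minlength=n_cand)
                n_lt = np.bincount(kpc[~dir_gt[keep]], minlength=n_cand)
                gt = (col[ps] > col[pp]) & keep
                lt = (col[ps] < col[pp]) & keep
                c_gt = np.bincount(pc, weights=gt, minlength=n_cand).astype(np.int64)
                c_lt = np.bincount(pc, weights=lt, minlength=n_cand).astype(np.int64)
            else:
                n_gt = n_lt = c_gt = c_lt = np.zeros(n_cand, dtype=np.int64)
            ok = (n_gt + n_lt) > 0
            p = np.ones(n_cand)
            p[ok] = np.atleast_1d(
                fisher_greater_p(c_gt[ok], c_lt[ok], n_gt[ok], n_lt[ok])
            )
            adj[:, s] = bh_adjust(p)
            with np.errstate(invalid="ignore", divide="ignore"):
                samp_frac = np.where(
                    c_gt + c_lt > 0, c_gt / np.maximum(c_gt + c_lt, 1), 0.0
                )
                back_frac = np.where(ok, n_gt / np.maximum(n_gt + n_lt, 1), 1.0)
            new_up = (adj[:, s] < individual_fdr) & (samp_frac > back_frac) & ok
            if np.array_equal(new_up, up_now):
                break
            up_now = new_up
        flags[:, s] = up_now
    idx = pd.Index(candidates, name="gene_id")
    return (
        pd.DataFrame(flags, index=idx, columns=cohort.columns),
        pd.DataFrame(adj, index=idx, columns=cohort.columns),
    )


def rankcomp_updeg(
    sample: pd.Series,
    candidates,
    background: StablePairSet,
    individual_fdr: float = 0.05,
    *,
    max_rounds: int = 1,
) -> pd.DataFrame:
    """Up-DEG calls for a single expression column.

    Convenience wrapper over :func:`call_updegs`; returns a DataFrame
    indexed by candidate gene with columns ``up`` (bool) and
    ``adjusted_p``.
    """
    cohort = sample.to_frame(name=sample.name or "sample")
    flags, adj = call_updegs(
        cohort, candidates, background, individual_fdr, max_rounds=max_rounds
    )
    return pd.DataFrame({"up": flags.iloc[:, 0], "adjusted_p": adj.iloc[:, 0]})


def binomial_population_p(k: int, n: int, cfg: BinomialTestConfig | None = None) -> float:
    """Upper binomial tail P(X >= k) for X ~ Binomial(n, P0).

    Equals ``1 - sum_{i<k} C(n,i) P0^i (1-P0)^(n-i)``: the probability of
    seeing at least k up-called samples out of n under the chance rate P0.
    """
    cfg = cfg or BinomialTestConfig()
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= k <= n:
        raise ValueError("k must lie in [0, n]")
    return float(binom.sf(k - 1, n, cfg.P0))


def build_signatures(
    catalog: dict[str, list[str]],
    per_cell_flags: dict[str, pd.DataFrame],
    cfg: BinomialTestConfig | None = None,
) -> SignatureSet:
    """Population-level filtering and the cross-cell-type uniqueness rule.

    ``per_cell_flags`` maps cell_type -> candidate-by-sample boolean frame
    of individual up calls (from :func:`call_updegs` on that type's
    cohort).  Per cell type, k = samples flagged up and n = total samples
    feed the binomial tail; BH adjustment is per cell type across its
    candidates; genes pass at adjusted p < ``population_fdr``.  Any gene
    passing for two or more cell types is then removed from all of them.
    """
    cfg = cfg or BinomialTestConfig()
    retained: dict[str, dict[str, float]] = {}
    for ct, genes in catalog.items():
        flags = per_cell_flags.get(ct)
        if flags is None or flags.shape[1] == 0:
            raise ValueError(f"cell type {ct!r} has no profiled samples")
        cand = [g for g in genes if g in flags.index]
        if len(cand) < len(genes):
            logger.warning(
                "%s: %d candidates missing from up-call table, dropped",
                ct, len(genes) - len(cand),
            )
        n = flags.shape[1]
        k = flags.loc[cand].sum(axis=1).to_numpy()
        p = np.array([binomial_population_p(int(ki), n, cfg) for ki in k])
        adj = bh_adjust(p)
        retained[ct] = {
            g: float(ap) for g, ap in zip(cand, adj) if ap < cfg.population_fdr
        }
    # uniqueness: drop genes retained for >= 2 cell types
    counts: dict[str, int] = {}
    for genes in retained.values():
        for g in genes:
            counts[g] = counts.get(g, 0) + 1
    shared = {g for g, c in counts.items() if c >= 2}
    if shared:
        logger.info("removing %d genes shared between cell types", len(shared))
    entries, provenance = {}, {}
    for ct in catalog:
        kept = [g for g in catalog[ct] if g in retained[ct] and g not in shared]
        if not kept:
            logger.warning("cell type %s has an empty signature; scoring disabled", ct)
        entries[ct] = kept
        provenance[ct] = {g: retained[ct][g] for g in kept}
    return SignatureSet(entries=entries, provenance=provenance)
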