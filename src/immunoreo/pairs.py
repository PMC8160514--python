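"""Highly stable gene pairs in a reference cohort.

A directed pair (greater, lesser) is *stable* when the strict ordering
``expr[greater] > expr[lesser]`` holds in at least a threshold fraction
(default 99%) of reference samples.  Within-sample orderings are invariant
to any monotone normalization, which is what makes the downstream scoring
robust to batch effects.  Ties satisfy neither direction, and the support
denominator is always the full reference sample count.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["StablePairSet", "find_stable_pairs"]


@dataclass
class StablePairSet:
    """Directed gene pairs with ordering support above a threshold.

    ``pairs`` maps (greater_gene, lesser_gene) -> support, the exact
    fraction of reference samples in which the strict ordering held.  At
    most one direction is stored per unordered pair; this is guaranteed by
    ``threshold > 0.5``.
    """

    pairs: dict[tuple[str, str], float]
    threshold: float
    reference_n: int
    _adjacency: dict[str, tuple[list[str], list[str]]] = field(
        default=None, repr=False, compare=False
    )

    def __len__(self) -> int:
        return len(self.pairs)

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return pair in self.pairs

    def partners(self, gene: str) -> tuple[list[str], list[str]]:
        """Return (genes below `gene`, genes above `gene`) in the reference.

        The first list holds partners h with (gene, h) stored (gene greater),
        the second partners h with (h, gene) stored (gene lesser).
        """
        if self._adjacency is None:
            adj: dict[str, tuple[list[str], list[str]]] = {}
            for g, h in self.pairs:
                adj.setdefault(g, ([], []))[0].append(h)
                adj.setdefault(h, ([], []))[1].append(g)
            object.__setattr__(self, "_adjacency", adj)
        return self._adjacency.get(gene, ([], []))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(g, h, s) for (g, h), s in self.pairs.items()],
            columns=["greater_gene", "lesser_gene", "support"],
        )

    def write(self, path) -> None:
        path = Path(path)
        with open(path, "wt") as fh:
            fh.write(f"# threshold: {self.threshold}\n")
            fh.write(f"# reference_n: {self.reference_n}\n")
            self.to_frame().to_csv(fh, sep="\t", index=False)

    @classmethod
    def read(cls, path) -> "StablePairSet":
        path = Path(path)
        meta = {}
        with open(path) as fh:
            for line in fh:
                if not line.startswith("#"):
                    break
                key, _, value = line[1:].partition(":")
                meta[key.strip()] = value.strip()
        df = pd.read_csv(path, sep="\t", comment="#")
        pairs = {
            (str(r.greater_gene), str(r.lesser_gene)): float(r.support)
            for r in df.itertuples()
        }
        return cls(pairs, float(meta["threshold"]), int(meta["reference_n"]))


def _support_count(threshold: float, n: int) -> int:
    """Minimum sample count for a pair to qualify: ceil(threshold * n),
    computed defensively against float representation of the product."""
    return int(math.ceil(threshold * n - 1e-9))


def find_stable_pairs(
    reference: pd.DataFrame,
    focus_genes,
    threshold: float = 0.99,
    *,
    all_pairs: bool = False,
    chunk: int = 256,
) -> StablePairSet:
    """Identify stable pairs between focus genes and all reference genes.

    For every pair (g, h) with g in ``focus_genes`` (or every gene when
    ``all_pairs=True``) and h any reference gene, the direction g > h is
    stored iff the strict ordering holds in at least ``threshold`` of the
    reference samples, and likewise for g < h (stored as (h, g)).  Pairs
    between two focus genes are examined once.

    The focus restriction exists because downstream scoring only ever
    consults pairs involving candidate marker genes; it reduces the cost
    from O(G^2 N) to O(M G N).
    """
    if not 0.5 < threshold <= 1.0:
        raise ValueError("threshold must lie in (0.5, 1]")
    n = reference.shape[1]
    if n < 2:
        raise ValueError("reference must have at least 2 samples")
    genes = reference.index
    if all_pairs:
        focus = list(genes)
    else:
        focus = [g for g in dict.fromkeys(focus_genes)]
        if not focus:
            raise ValueError("focus_genes is empty")
        missing = [g for g in focus if g not in genes]
        if missing:
            logger.warning("%d focus genes absent from reference, dropped", len(missing))
            focus = [g for g in focus if g in genes]
            if not focus:
                raise ValueError("no focus genes present in the reference matrix")

    values = reference.to_numpy(dtype=float)
    gene_pos = {g: i for i, g in enumerate(genes)}
    focus_idx = np.array([gene_pos[g] for g in focus])
    focus_set = set(focus)
    need = _support_count(threshold, n)
    gene_arr = np.asarray(genes, dtype=object)

    pairs: dict[tuple[str, str], float] = {}
    for start in range(0, len(focus_idx), chunk):
        idx = focus_idx[start : start + chunk]
        block = values[idx][:, None, :]  # (chunk, 1, samples)
        gt = (block > values[None, :, :]).sum(axis=2)  # focus > other counts
        lt = (block < values[None, :, :]).sum(axis=2)
        for row, fi in enumerate(idx):
            g = genes[fi]
            up = np.where(gt[row] >= need)[0]
            down = np.where(lt[row] >= need)[0]
            for j in up:
                h = gene_arr[j]
                if h == g or (h in focus_set and (h, g) in pairs):
                    continue
                pairs[(g, h)] = gt[row, j] / n
            for j in down:
                h = gene_arr[j]
                if h == g or (h in focus_set and (h, g) in pairs):
                    continue
                pairs[(h, g)] = lt[row, j] / n
    logger.info(
        "stable pairs: %d pairs at threshold %.3f over %d reference samples",
        len(pairs), threshold, n,
    )
    return StablePairSet(pairs=pairs, threshold=threshold, reference_n=n)
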