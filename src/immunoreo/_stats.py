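"""Shared statistical primitives: one-sided hypergeometric tails and FDR control.

All Fisher-exact machinery in the package reduces to the upper tail of a
hypergeometric distribution, evaluated here in vectorized form.  Multiple
testing is controlled with the Benjamini–Hochberg step-up procedure via
statsmodels.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

__all__ = ["fisher_greater_p", "bh_adjust"]

# Floor applied to Fisher p-values before taking -log10, so scores stay finite.
P_FLOOR = 1e-300


def fisher_greater_p(c, d, a, b):
    """One-sided Fisher exact p-value for the 2x2 table [[c, d], [a, b]].

    Rows are (query sample, reference background); columns are the two
    ordering outcomes (signature gene above partner, signature gene below
    partner).  The alternative is that the sample row is enriched for the
    first column, i.e. the sample shows more "signature gene > partner"
    orderings than the background would predict.

    Parameters are array-like and broadcast together; the return value is a
    float or ndarray of p-values in (0, 1].

    Conditioning on all margins, the first cell follows a hypergeometric
    law ``Hypergeom(M=a+b+c+d, K=a+c, n=c+d)``; the p-value is ``P(X >= c)``.
    """
    c = np.asarray(c, dtype=np.int64)
    d = np.asarray(d, dtype=np.int64)
    a = np.asarray(a, dtype=np.int64)
    b = np.asarray(b, dtype=np.int64)
    if np.any(a < 0) or np.any(b < 0) or np.any(c < 0) or np.any(d < 0):
        raise ValueError("contingency counts must be non-negative")
    M = a + b + c + d
    if np.any(M == 0):
        raise ValueError("all-zero contingency table")
    # sf can return exact 0.0 only through underflow; clip into (0, 1]
    p = np.clip(hypergeom.sf(c - 1, M, a + c, c + d), P_FLOOR, 1.0)
    return float(p) if p.ndim == 0 else p


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values (empty input passes through)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]
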