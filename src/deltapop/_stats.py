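"""Small statistical helpers used by several modules."""

from __future__ import annotations

import numpy as np


def benjamini_hochberg(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg q-values (step-up, monotone in p-value rank)."""
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def empirical_pvalues(observed: np.ndarray, null: np.ndarray) -> np.ndarray:
    """Add-one empirical p-values against a finite null sample.

    ``p = (1 + #{null >= obs}) / (N + 1)``; ties in the null count as
    exceedances, so p is never zero and lies in (0, 1].
    """
    null = np.sort(np.asarray(null, dtype=float))
    if null.size == 0:
        raise ValueError("empty null distribution")
    obs = np.asarray(observed, dtype=float)
    n_ge = null.size - np.searchsorted(null, obs, side="left")
    return (1.0 + n_ge) / (null.size + 1.0)


def standardize(x: np.ndarray, ddof: int = 0) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    sd = x.std(ddof=ddof)
    if sd == 0:
        raise ValueError("cannot standardize a constant vector")
    return (x - x.mean()) / sd
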