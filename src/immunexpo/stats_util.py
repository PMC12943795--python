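"""Small shared statistical helpers."""

from __future__ import annotations

import numpy as np

P_FLOOR = 1e-300  # avoid downstream log underflow


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1).

    NaNs are ignored for ranking and returned as NaN.
    """
    p = np.asarray(pvals, dtype=float)
    out = np.full(p.shape, np.nan)
    obs = ~np.isnan(p)
    v = p[obs]
    m = v.size
    if m == 0:
        return out
    order = np.argsort(v, kind="mergesort")
    ranked = v[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    res = np.empty(m)
    res[order] = np.minimum(adj, 1.0)
    out[obs] = res
    return out


def floor_p(p):
    return np.maximum(np.asarray(p, dtype=float), P_FLOOR)
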