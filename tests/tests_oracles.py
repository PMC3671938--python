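"""Shared brute-force reference implementations used by multiple tests."""

import numpy as np


def brute_hotspots(div, window=20, ratio=0.5):
    """Score every centered window explicitly; O(L * window)."""
    L = div.length
    hot = np.zeros(L, bool)
    for start in range(L - window + 1):
        o = div.obs[start:start + window].sum()
        e = div.exp[start:start + window].sum()
        bad = (~div.valid[start:start + window]).any()
        if e > 0 and o <= ratio * e and not bad:
            hot[start + window // 2] = True
    runs, s = [], None
    for i in range(L + 1):
        on = i < L and hot[i]
        if on and s is None:
            s = i
        elif not on and s is not None:
            runs.append((s, i))
            s = None
    return runs
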