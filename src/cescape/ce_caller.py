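"""Conserved-element calling from an observed/expected divergence track.

A 20 bp window sliding at 1 bp steps qualifies as a conservation hotspot
when its summed observed substitutions are at most half (ratio parameter)
the summed expected substitutions.  Hotspot positions (the union of
qualifying windows) are merged into maximal runs, expanded by 10 bp,
overlap-merged, and kept when longer than 30 bp.  Windows containing any
masked base are skipped entirely to avoid edge artifacts at exon borders.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome_io import GenomeMask
from .subst_model import DivergenceTrack


@dataclass
class ConservedElement:
    chrom: str
    start: int
    end: int
    score: float          # sum(obs)/sum(exp) over the element

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2

    @property
    def length(self) -> int:
        return self.end - self.start


def _window_sums(v: np.ndarray, w: int) -> np.ndarray:
    c = np.concatenate(([0.0], np.cumsum(v)))
    return c[w:] - c[:-w]


def call_hotspots(div: DivergenceTrack, window: int = 20, ratio: float = 0.5,
                  mask: GenomeMask | None = None) -> list:
    """Maximal runs of hotspot loci.

    Each locus is scored by the 20 bp window centered on it (the window
    [l - w//2, l + w - w//2)); the locus is a hotspot iff that window has
    sum(obs) <= ratio * sum(exp), sum(exp) > 0, and contains no
    masked/invalid base.  Scoring the center (rather than taking the
    union of qualifying windows) keeps hotspot runs half a window
    narrower than the conserved span on each side — which the subsequent
    half-window (10 bp) expansion in refine_ces exactly compensates.
    """
    L = div.length
    if window > L:
        return []
    bad = ~div.valid
    if mask is not None:
        bad = bad | mask.mask_vector(div.chrom, L)
    obs_w = _window_sums(div.obs, window)
    exp_w = _window_sums(div.exp, window)
    bad_w = _window_sums(bad.astype(float), window)
    qual = (exp_w > 0) & (obs_w <= ratio * exp_w) & (bad_w == 0)
    hot = np.zeros(L, dtype=bool)
    hot[window // 2: window // 2 + len(qual)] = qual
    return _runs(hot)


def _runs(flags: np.ndarray) -> list:
    edges = np.flatnonzero(np.diff(np.concatenate(
        ([0], flags.view(np.int8), [0]))))
    return [(int(edges[i]), int(edges[i + 1])) for i in range(0, len(edges), 2)]


def refine_ces(hotspots: list, div: DivergenceTrack, expand: int = 10,
               min_len: int = 30) -> list:
    """Expand, merge (including bookended intervals), filter by length > min_len,
    and rescore each surviving element as sum(obs)/sum(exp)."""
    if not hotspots:
        return []
    grown = sorted((max(0, s - expand), min(div.length, e + expand))
                   for s, e in hotspots)
    merged = [list(grown[0])]
    for s, e in grown[1:]:
        if s <= merged[-1][1]:          # overlap or bookended
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    out = []
    cobs = np.concatenate(([0.0], np.cumsum(div.obs)))
    cexp = np.concatenate(([0.0], np.cumsum(div.exp)))
    for s, e in merged:
        if e - s <= min_len:
            continue
        tot_exp = cexp[e] - cexp[s]
        score = (cobs[e] - cobs[s]) / tot_exp if tot_exp > 0 else np.nan
        out.append(ConservedElement(div.chrom, s, e, score))
    return out


def call_ces(div: DivergenceTrack, window: int = 20, ratio: float = 0.5,
             expand: int = 10, min_len: int = 30,
             mask: GenomeMask | None = None) -> list:
    return refine_ces(call_hotspots(div, window, ratio, mask), div,
                      expand, min_len)


def ces_to_bed(ces: list) -> pd.DataFrame:
    return pd.DataFrame({
        "chrom": [c.chrom for c in ces],
        "start": [c.start for c in ces],
        "end": [c.end for c in ces],
        "name": [f"CE{i}" for i in range(len(ces))],
        "score": [int(round(1000 * min(1.0, 1.0 - c.score))) for c in ces],
        "strand": ".",
    })


# ---------------------------------------------------------------------------
# Recovery scoring against planted truth


def match_to_truth(ces: list, truth: list, min_jaccard: float = 0.5):
    """Greedy interval matching; returns (sensitivity, false_call_fraction,
    matches) where matches pairs CE index with truth index."""
    matches = []
    used = set()
    for ci, ce in enumerate(ces):
        best, best_j = None, 0.0
        for ti, (s, e) in enumerate(truth):
            if ti in used:
                continue
            inter = max(0, min(ce.end, e) - max(ce.start, s))
            union = (ce.end - ce.start) + (e - s) - inter
            j = inter / union if union else 0.0
            if j > best_j:
                best, best_j = ti, j
        if best is not None and best_j >= min_jaccard:
            matches.append((ci, best, best_j))
            used.add(best)
    sensitivity = len(used) / len(truth) if truth else np.nan
    matched_ces = {ci for ci, _, _ in matches}
    # a call is false when it does not even touch a planted core
    false_calls = sum(
        1 for ci, ce in enumerate(ces)
        if ci not in matched_ces and not any(
            min(ce.end, e) - max(ce.start, s) > 0 for s, e in truth))
    false_fraction = false_calls / len(ces) if ces else 0.0
    return sensitivity, false_fraction, matches
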