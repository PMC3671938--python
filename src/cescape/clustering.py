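"""Clustering of conserved elements by epigenetic context and by local
sequence composition.

Epigenetic clustering works on a CE x mark matrix of mean normalized
signal (k-means, Euclidean, 12 clusters by default).  Sequence clustering
encodes the +-100 bp window around each CE center as 100 non-overlapping
2 bp steps scored 0/1/2 by their G+C count — which averages out the
signature of 2 bp-periodic microsatellites — and k-means those vectors
(20 clusters by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans

from .genome_io import encode_seq
from .profiles import SignalTrackNorm


@dataclass
class ClusterAssignment:
    labels: np.ndarray
    k: int
    seed: int
    inertia: float
    item_ids: np.ndarray | None = None


def epi_feature_matrix(ces, tracks: dict):
    """CE x mark matrix of mean normalized signal over each CE interval.

    CEs overlapping zero scored bins are dropped (with a warning); the
    returned index maps surviving rows back to the input CE list.
    """
    names = list(tracks)
    binsize = tracks[names[0]].binsize
    rows, kept = [], []
    for i, ce in enumerate(ces):
        b0 = ce.start // binsize
        b1 = max(b0 + 1, -(-ce.end // binsize))
        vals = np.array([np.nanmean(tracks[t].values[b0:b1]) for t in names]) \
            if b1 <= tracks[names[0]].values.size else np.full(len(names), np.nan)
        if np.isnan(vals).all():
            warnings.warn(f"CE {ce.start}-{ce.end} overlaps no scored bins; dropped")
            continue
        rows.append(vals)
        kept.append(i)
    X = np.asarray(rows)
    return X, np.asarray(kept, dtype=np.int64), names


def kmeans_cluster(X: np.ndarray, k: int, seed: int = 0,
                   n_init: int = 25) -> ClusterAssignment:
    """k-means++ with n_init restarts, deterministic under the seed."""
    if k >= X.shape[0]:
        raise ValueError("k must be smaller than the number of rows")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    labels = km.fit_predict(X)
    return ClusterAssignment(labels, k, seed, float(km.inertia_))


def dinuc_gc_encode(seq, ces, halfwidth: int = 100):
    """Per-CE vector of G+C counts in non-overlapping 2 bp steps around the
    element midpoint.  Windows containing N (or running off the sequence)
    are excluded; returns (vectors, kept CE indices)."""
    codes = seq if isinstance(seq, np.ndarray) else encode_seq(seq)
    is_gc = np.isin(codes, (1, 2)).astype(np.int8)
    vectors, kept = [], []
    for i, ce in enumerate(ces):
        c = ce.center if hasattr(ce, "center") else int(ce)
        s, e = c - halfwidth, c + halfwidth
        if s < 0 or e > len(codes) or (codes[s:e] >= 4).any():
            continue
        v = is_gc[s:e].reshape(halfwidth, 2).sum(axis=1)
        vectors.append(v)
        kept.append(i)
    return np.asarray(vectors, dtype=np.int8), np.asarray(kept, dtype=np.int64)
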