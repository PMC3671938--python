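"""Signed minimal-distance profiling machinery.

Every genomic position is assigned to the offset of its *nearest* anchor
locus (signed, downstream positive), so each base contributes to exactly
one offset — the partition property that keeps composition profiles
unbiased.  The same machinery produces nucleotide-composition profiles,
mean-signal profiles, percentile track normalization, percentile peak
calling, and site-set enrichment curves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .genome_io import GenomeMask, SignalTrackRaw, encode_seq


@dataclass
class DistanceProfile:
    offsets: np.ndarray             # signed bp (bin left edges for binned)
    value: np.ndarray               # (n_offsets,) or (n_offsets, n_categories)
    ci_lo: np.ndarray
    ci_hi: np.ndarray
    n: np.ndarray                   # positions contributing per offset
    categories: list | None = None

    def to_frame(self) -> pd.DataFrame:
        if self.categories is None:
            return pd.DataFrame({"offset": self.offsets, "value": self.value,
                                 "ci_lo": self.ci_lo, "ci_hi": self.ci_hi,
                                 "n": self.n})
        rows = []
        for j, cat in enumerate(self.categories):
            rows.append(pd.DataFrame({
                "offset": self.offsets, "category": cat,
                "value": self.value[:, j], "ci_lo": self.ci_lo[:, j],
                "ci_hi": self.ci_hi[:, j], "n": self.n}))
        return pd.concat(rows, ignore_index=True)


def nearest_signed_distance(positions, centers, orientation=None) -> np.ndarray:
    """Signed distance from each position to its nearest locus center.

    Sign is genomic (position right of the locus is positive) unless a
    per-locus strand array of +-1 flips it.  Equidistant ties go to the
    locus with the smaller coordinate.
    """
    positions = np.asarray(positions, dtype=np.int64)
    centers = np.sort(np.asarray(centers, dtype=np.int64))
    if len(centers) == 0:
        raise ValueError("empty locus set")
    idx = np.searchsorted(centers, positions)
    left = np.clip(idx - 1, 0, len(centers) - 1)
    right = np.clip(idx, 0, len(centers) - 1)
    dl = np.abs(positions - centers[left])
    dr = np.abs(positions - centers[right])
    # tie (dl == dr) resolves to the smaller-coordinate locus, i.e. left
    use_left = dl <= dr
    nearest = np.where(use_left, left, right)
    d = positions - centers[nearest]
    if orientation is not None:
        orientation = np.asarray(orientation)
        d = d * orientation[nearest]
    return d


def _assign_offsets(L, centers, halfwidth, mask=None, chrom="chr",
                    orientation=None):
    """Positions within halfwidth of any center, with their signed offsets."""
    pos = np.arange(L, dtype=np.int64)
    d = nearest_signed_distance(pos, centers, orientation)
    keep = np.abs(d) <= halfwidth
    if mask is not None:
        keep &= ~mask.mask_vector(chrom, L)
    return pos[keep], d[keep]


def _binom_ci(k, n, z=1.959964):
    with np.errstate(divide="ignore", invalid="ignore"):
        p = k / n
        half = z * np.sqrt(p * (1 - p) / n)
    return p - half, p + half


def composition_profile(seq, centers, mask: GenomeMask | None = None,
                        halfwidth: int = 1000, binwidth: int = 1,
                        chrom: str = "chr") -> DistanceProfile:
    """Per-offset base frequencies around anchor centers with binomial CIs."""
    codes = seq if isinstance(seq, np.ndarray) else encode_seq(seq)
    pos, d = _assign_offsets(len(codes), centers, halfwidth, mask, chrom)
    b = codes[pos]
    known = b < 4
    pos, d, b = pos[known], d[known], b[known]
    nb = (2 * halfwidth) // binwidth + 1
    bins = (d + halfwidth) // binwidth
    counts = np.zeros((nb, 4))
    for base in range(4):
        counts[:, base] = np.bincount(bins[b == base], minlength=nb)
    n = counts.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        freq = counts / n[:, None]
    lo, hi = _binom_ci(counts, n[:, None])
    offsets = np.arange(nb) * binwidth - halfwidth
    return DistanceProfile(offsets, freq, lo, hi, n, categories=list("ACGT"))


def signal_profile(values: np.ndarray, centers, mask: GenomeMask | None = None,
                   halfwidth: int = 1000, binwidth: int = 1,
                   chrom: str = "chr",
                   valid: np.ndarray | None = None) -> DistanceProfile:
    """Mean of a per-bp value array per signed offset, normal-approx CI."""
    values = np.asarray(values, dtype=float)
    pos, d = _assign_offsets(len(values), centers, halfwidth, mask, chrom)
    if valid is not None:
        ok = valid[pos]
        pos, d = pos[ok], d[ok]
    v = values[pos]
    fin = np.isfinite(v)
    pos, d, v = pos[fin], d[fin], v[fin]
    nb = (2 * halfwidth) // binwidth + 1
    bins = (d + halfwidth) // binwidth
    n = np.bincount(bins, minlength=nb).astype(float)
    s1 = np.bincount(bins, weights=v, minlength=nb)
    s2 = np.bincount(bins, weights=v * v, minlength=nb)
    with np.errstate(divide="ignore", invalid="ignore"):
        mean = s1 / n
        var = np.maximum(s2 / n - mean ** 2, 0.0)
        half = 1.959964 * np.sqrt(var / n)
    offsets = np.arange(nb) * binwidth - halfwidth
    return DistanceProfile(offsets, mean, mean - half, mean + half, n)


# ---------------------------------------------------------------------------
# Track normalization and peak calling


@dataclass
class SignalTrackNorm:
    chrom: str
    binsize: int
    values: np.ndarray              # percentile in [0,1]; NaN where unscored

    def per_bp(self, length=None):
        out = np.repeat(self.values, self.binsize)
        return out if length is None else out[:length]


def normalize_track(raw: SignalTrackRaw, mask: GenomeMask | None = None,
                    presmooth: int = 0) -> SignalTrackNorm:
    """Genome-wide percentile (rank / n, average ranks on ties) over
    unmasked bins, after an optional overlapping running-mean presmooth
    (e.g. 200 bp for DHS-like data).  Invariant under any strictly
    monotone transform of the input."""
    v = raw.values.astype(float).copy()
    if presmooth:
        w = max(1, presmooth // raw.binsize)
        kernel = np.ones(w) / w
        v = np.convolve(v, kernel, mode="same")
    scored = np.isfinite(v)
    if mask is not None:
        mv = mask.mask_vector(raw.chrom, raw.n_bins * raw.binsize)
        scored &= ~mv.reshape(raw.n_bins, raw.binsize).any(axis=1)
    out = np.full(raw.n_bins, np.nan)
    if scored.sum():
        sv = v[scored]
        if np.ptp(sv) == 0:            # degenerate flat track
            out[scored] = 0.5
        else:
            out[scored] = rankdata(sv) / scored.sum()
    return SignalTrackNorm(raw.chrom, raw.binsize, out)


@dataclass
class PeakSet:
    centers: np.ndarray
    intervals: list
    threshold: float
    source: str = ""


def call_peaks(tracks, percentile: float, tss=None, tss_mindist: int = 1000,
               mask: GenomeMask | None = None) -> PeakSet:
    """Peaks from one or more normalized replicate/stage tracks.

    A bin qualifies when its value exceeds the percentile in at least one
    track, is unmasked/scored, and (when a TSS list is given) lies further
    than tss_mindist from the nearest TSS.  Maximal runs of qualifying
    bins become intervals; the center is the maximal-value bin (midpoint
    of the run of maxima on ties).
    """
    if isinstance(tracks, SignalTrackNorm):
        tracks = [tracks]
    if not 0 < percentile < 1:
        raise ValueError("percentile must be in (0,1)")
    binsize = tracks[0].binsize
    n = min(t.values.size for t in tracks)
    mat = np.vstack([t.values[:n] for t in tracks])
    with np.errstate(invalid="ignore"):
        qual = np.nanmax(mat, axis=0) > percentile
    qual &= np.isfinite(mat).any(axis=0)
    if tss is not None and len(tss):
        centers_bp = np.arange(n) * binsize + binsize // 2
        d = np.abs(nearest_signed_distance(centers_bp, tss))
        qual &= d > tss_mindist
    best = np.nanmax(np.where(np.isfinite(mat), mat, -np.inf), axis=0)
    intervals, centers = [], []
    edges = np.flatnonzero(np.diff(np.concatenate(
        ([0], qual.view(np.int8), [0]))))
    for i in range(0, len(edges), 2):
        s, e = int(edges[i]), int(edges[i + 1])
        vals = best[s:e]
        top = np.flatnonzero(vals == vals.max())
        cbin = s + int(round(top.mean()))
        intervals.append((s * binsize, e * binsize))
        centers.append(cbin * binsize + binsize // 2)
    import warnings
    if not intervals:
        warnings.warn("no bins qualify at this percentile")
    return PeakSet(np.array(centers, dtype=np.int64), intervals, percentile)


def site_enrichment(sites, centers, mask: GenomeMask | None = None,
                    halfwidth: int = 1000, binwidth: int = 50,
                    genome_length: int | None = None,
                    chrom: str = "chr") -> pd.DataFrame:
    """Per-distance-bin log2(observed sites / expected under uniformity).

    Expected counts allocate the total number of assignable sites in
    proportion to the assignable (unmasked, within halfwidth) bp per bin.
    """
    sites = np.asarray(sites, dtype=np.int64)
    if len(sites) == 0:
        raise ValueError("empty site set")
    if genome_length is None:
        genome_length = int(max(sites.max(), np.max(centers))) + halfwidth
    pos, d = _assign_offsets(genome_length, centers, halfwidth, mask, chrom)
    nb = (2 * halfwidth) // binwidth + 1
    bp_per_bin = np.bincount((d + halfwidth) // binwidth, minlength=nb)
    in_range = np.isin(sites, pos)
    ds = nearest_signed_distance(sites[in_range], centers)
    obs = np.bincount((ds + halfwidth) // binwidth, minlength=nb)
    total = obs.sum()
    exp = total * bp_per_bin / bp_per_bin.sum()
    # bins with almost no assignable bp cannot support an estimate; a
    # pseudo-count there would fabricate enrichment out of nothing
    with np.errstate(divide="ignore", invalid="ignore"):
        log2e = np.where(exp >= 0.5, np.log2(np.maximum(obs, 0.5) / exp),
                         np.nan)
    offsets = np.arange(nb) * binwidth - halfwidth
    return pd.DataFrame({"offset": offsets, "observed": obs, "expected": exp,
                         "log2_enrichment": log2e})
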