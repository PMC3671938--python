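"""k-mer and microsatellite profiles around conserved elements with
composition normalization.

The raw enrichment of a k-mer at a distance bin is log2 of its frequency
there over its global frequency.  The normalized enrichment divides each
frequency first by the product of the single-nucleotide frequencies of
the same stratum, so that enrichment driven purely by base composition
(e.g. abundant CA repeats inside GC-elevated flanks) cancels and only the
residual repeat structure remains — the contrast between the raw and
normalized curves is the test of whether a repeat family is specifically
enriched or just rides the composition gradient.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome_io import GenomeMask, encode_seq
from .profiles import nearest_signed_distance, signal_profile

_COMP = str.maketrans("ACGT", "TGCA")


def revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


def kmer_ids(codes: np.ndarray, k: int) -> np.ndarray:
    """Base-4 id of the k-mer starting at each position (valid where all k
    bases are plain ACGT; invalid starts get -1)."""
    L = len(codes)
    ids = np.zeros(L - k + 1, dtype=np.int64)
    valid = np.ones(L - k + 1, dtype=bool)
    for j in range(k):
        part = codes[j:L - k + 1 + j].astype(np.int64)
        valid &= part < 4
        ids = ids * 4 + np.where(part < 4, part, 0)
    ids[~valid] = -1
    return ids


def kmer_to_id(kmer: str) -> int:
    i = 0
    for ch in kmer:
        i = i * 4 + "ACGT".index(ch)
    return i


def id_to_kmer(i: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append("ACGT"[i % 4])
        i //= 4
    return "".join(reversed(out))


def _bin_assignment(L, centers, halfwidth, binwidth, mask, chrom):
    pos = np.arange(L, dtype=np.int64)
    d = nearest_signed_distance(pos, centers)
    bins = np.where(np.abs(d) <= halfwidth,
                    (d + halfwidth) // binwidth, -1)
    if mask is not None:
        bins[mask.mask_vector(chrom, L)] = -1
    return bins


def kmer_distance_freq(seq, ces, k: int, binwidth: int = 50,
                       halfwidth: int = 1000, mask: GenomeMask | None = None,
                       chrom: str = "chr", stride: int = 1):
    """Per-distance-bin k-mer frequencies around CE centers.

    Every unmasked position is assigned to the signed-distance bin of its
    nearest CE center; a k-mer start belongs to the bin of its first base
    and is dropped if any of its k bases is masked or ambiguous.  Returns
    (freq (n_bins, 4^k), n_starts, compositions (n_bins, 4), offsets).
    """
    if k > 8:
        raise ValueError("k must be <= 8")
    codes = seq if isinstance(seq, np.ndarray) else encode_seq(seq)
    centers = np.array([c.center if hasattr(c, "center") else int(c)
                        for c in ces], dtype=np.int64)
    bins = _bin_assignment(len(codes), centers, halfwidth, binwidth,
                           mask, chrom)
    nb = (2 * halfwidth) // binwidth + 1
    # single-nucleotide composition per bin over assigned, unambiguous bases
    known = codes < 4
    comp = np.zeros((nb, 4))
    sel = (bins >= 0) & known
    comp_flat = np.bincount(bins[sel] * 4 + codes[sel].astype(np.int64),
                            minlength=nb * 4)
    comp = comp_flat.reshape(nb, 4).astype(float)
    comp /= np.maximum(comp.sum(axis=1, keepdims=True), 1)
    ids = kmer_ids(codes, k)
    ok = ids >= 0
    # a start is dropped when any covered base is masked (bin -1)
    covered_bad = np.zeros(len(ids), dtype=bool)
    bad = bins < 0
    for j in range(k):
        covered_bad |= bad[j:len(codes) - k + 1 + j]
    ok &= ~covered_bad
    if stride > 1:
        keep = np.zeros(len(ids), dtype=bool)
        keep[::stride] = True
        ok &= keep
    start_bins = bins[: len(ids)]
    sel = ok & (start_bins >= 0)
    counts = np.bincount(start_bins[sel] * (4 ** k) + ids[sel],
                         minlength=nb * 4 ** k).reshape(nb, 4 ** k)
    n_starts = counts.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        freq = counts / np.maximum(n_starts, 1)[:, None]
    offsets = np.arange(nb) * binwidth - halfwidth
    return freq.astype(float), n_starts, comp, offsets


def kmer_bin_frequencies(bin_seqs, k: int):
    """k-mer frequencies, start counts and base compositions for explicit
    per-stratum sequences (no distance assignment) — the building block
    kmer_distance_freq reduces to, useful for composition-matched nulls."""
    nb = len(bin_seqs)
    freq = np.zeros((nb, 4 ** k))
    n_starts = np.zeros(nb, dtype=np.int64)
    comp = np.zeros((nb, 4))
    for b, seq in enumerate(bin_seqs):
        codes = seq if isinstance(seq, np.ndarray) else encode_seq(seq)
        ids = kmer_ids(codes, k)
        counts = np.bincount(ids[ids >= 0], minlength=4 ** k)
        n_starts[b] = counts.sum()
        if n_starts[b]:
            freq[b] = counts / n_starts[b]
        known = codes < 4
        comp[b] = np.bincount(codes[known].astype(np.int64), minlength=4)
        comp[b] /= max(known.sum(), 1)
    return freq, n_starts, comp


def normalized_enrichment(freq: np.ndarray, n_starts: np.ndarray,
                          compositions: np.ndarray, k: int,
                          kmers=None) -> pd.DataFrame:
    """Raw and composition-normalized log2 enrichment per (k-mer, bin).

    raw = log2(f_bin / f_global); norm divides each frequency by the
    product of the single-base frequencies of the same stratum first.
    Zero-frequency cells get a pseudo-frequency 0.5/n_starts (flagged).
    """
    nb = freq.shape[0]
    total = n_starts.sum()
    f_global = (freq * n_starts[:, None]).sum(axis=0) / max(total, 1)
    if kmers is None:
        ids = np.arange(4 ** k)
    else:
        ids = np.array([kmer_to_id(m) for m in kmers])
    w = n_starts / max(total, 1)
    rows = []
    for i in ids:
        kmer = id_to_kmer(int(i), k)
        bases = [int(c) for c in encode_seq(kmer)]
        fg = f_global[i]
        fg_pseudo = fg if fg > 0 else 0.5 / max(total, 1)
        # composition-normalized ratio per bin; the global baseline is the
        # start-weighted mean of the per-bin ratios, so that a sequence
        # that is i.i.d. within each stratum scores exactly 0 everywhere
        # (pooling compositions across strata first would leave a Jensen
        # residual wherever composition varies between bins)
        pb = np.array([np.prod([compositions[b, base] for base in bases])
                       for b in range(nb)])
        f_use = np.where(freq[:, i] > 0, freq[:, i],
                         0.5 / np.maximum(n_starts, 1))
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(pb > 0, f_use / pb, np.nan)
        baseline = np.nansum(ratio * w)
        for b in range(nb):
            if n_starts[b] == 0:
                continue
            f = freq[b, i]
            raw = np.log2(f_use[b] / fg_pseudo)
            norm = np.log2(ratio[b] / baseline) \
                if np.isfinite(ratio[b]) and baseline > 0 else np.nan
            rows.append({"kmer": kmer, "bin": b, "freq": f,
                         "raw_log2": raw, "norm_log2": norm,
                         "n_starts": int(n_starts[b]),
                         "zero_flagged": f == 0})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Tandem repeats


@dataclass
class RepeatSet:
    motif: str
    min_units: int
    intervals: list

    @property
    def centers(self) -> np.ndarray:
        return np.array([(s + e) // 2 for s, e in self.intervals],
                        dtype=np.int64)


def find_repeats(seq: str, motif: str, min_units: int) -> RepeatSet:
    """Maximal tandem runs of an exact motif (this phase only; call again
    with rotated/reverse-complemented motifs and merge for figure-style
    repeat families)."""
    if len(motif) > 6:
        raise ValueError("motif length must be <= 6")
    seq = seq if isinstance(seq, str) else "".join(seq)
    pat = re.compile(f"(?:{re.escape(motif)}){{{min_units},}}")
    intervals = [(m.start(), m.end()) for m in pat.finditer(seq)]
    return RepeatSet(motif, min_units, intervals)


def repeat_family(seq: str, motif: str, min_units: int,
                  include_revcomp: bool = True) -> RepeatSet:
    """Union of maximal runs over all phases (rotations) of the motif and,
    optionally, of its reverse complement — e.g. (CA)3 or (AC)3."""
    motifs = {motif[i:] + motif[:i] for i in range(len(motif))}
    if include_revcomp:
        rc = revcomp(motif)
        motifs |= {rc[i:] + rc[:i] for i in range(len(rc))}
    ivs = []
    for m in sorted(motifs):
        ivs.extend(find_repeats(seq, m, min_units).intervals)
    ivs.sort()
    merged = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return RepeatSet(motif, min_units, [tuple(x) for x in merged])


def divergence_around_repeats(div, reps: RepeatSet, halfwidth: int = 1000,
                              binwidth: int = 20):
    """Observed and expected divergence profiles around repeat centers."""
    obs = signal_profile(div.obs, reps.centers, halfwidth=halfwidth,
                         binwidth=binwidth, valid=div.valid)
    exp = signal_profile(div.exp, reps.centers, halfwidth=halfwidth,
                         binwidth=binwidth, valid=div.valid)
    return obs, exp
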