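"""Readers, writers and interval-mask logic shared by the whole pipeline.

All coordinates are 0-based, half-open, matching BED.  The alignment
container is reference-projected: columns where the reference species is
gapped are dropped, so every statistic downstream can be indexed directly
by reference position.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import AlignIO, SeqIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

MASK_LABELS = ("exon", "repeat")

# ---------------------------------------------------------------------------
# GenomeMask


@dataclass
class GenomeMask:
    """Sorted, non-overlapping exclusion intervals (exonic / repetitive loci).

    ``intervals`` maps ``(chrom, label)`` to two int arrays (starts, ends)
    kept sorted and merged, so membership queries are O(log n) via bisection.
    """

    intervals: dict = field(default_factory=dict)

    @classmethod
    def from_tuples(cls, tuples) -> "GenomeMask":
        """Build from an iterable of (chrom, start, end, label)."""
        buckets: dict = {}
        for chrom, start, end, label in tuples:
            if label not in MASK_LABELS:
                raise ValueError(f"unknown mask label {label!r}")
            if end <= start:
                raise ValueError(f"empty interval {chrom}:{start}-{end}")
            buckets.setdefault((chrom, label), []).append((start, end))
        mask = cls()
        for key, ivs in buckets.items():
            mask.intervals[key] = _merge_intervals(ivs)
        return mask

    @classmethod
    def read_bed(cls, path, label="exon") -> "GenomeMask":
        df = pd.read_csv(path, sep="\t", header=None, comment="#",
                         usecols=[0, 1, 2], names=["chrom", "start", "end"])
        return cls.from_tuples(
            (r.chrom, int(r.start), int(r.end), label) for r in df.itertuples())

    def chroms(self):
        return sorted({chrom for chrom, _ in self.intervals})

    def is_masked(self, chrom, positions) -> np.ndarray:
        """Vectorized membership: True where a position falls in any interval."""
        positions = np.asarray(positions, dtype=np.int64)
        hit = np.zeros(positions.shape, dtype=bool)
        for label in MASK_LABELS:
            arr = self.intervals.get((chrom, label))
            if arr is None:
                continue
            starts, ends = arr
            idx = np.searchsorted(starts, positions, side="right") - 1
            ok = idx >= 0
            hit[ok] |= positions[ok] < ends[idx[ok]]
        return hit

    def mask_vector(self, chrom, length) -> np.ndarray:
        """Boolean vector of given length, True at masked positions."""
        out = np.zeros(length, dtype=bool)
        for label in MASK_LABELS:
            arr = self.intervals.get((chrom, label))
            if arr is None:
                continue
            for s, e in zip(*arr):
                out[max(0, s):min(length, e)] = True
        return out


def _merge_intervals(ivs):
    ivs = sorted(ivs)
    merged = [list(ivs[0])]
    for s, e in ivs[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    arr = np.array(merged, dtype=np.int64)
    return arr[:, 0].copy(), arr[:, 1].copy()


def apply_mask(positions, mask: GenomeMask, chrom=None):
    """Drop positions overlapping any mask interval.

    ``positions`` is either an iterable of (chrom, pos) pairs, or a plain
    position iterable together with ``chrom``.  When the mask names any
    chromosomes at all, positions on chromosomes outside that namespace are
    outside the analyzed coordinate system: they are dropped with a warning.
    An entirely empty mask is the identity.
    """
    if chrom is not None:
        pos = np.asarray(sorted(positions), dtype=np.int64)
        return set(pos[~mask.is_masked(chrom, pos)].tolist())
    by_chrom: dict = {}
    for c, p in positions:
        by_chrom.setdefault(c, []).append(p)
    known = set(mask.chroms())
    out = set()
    for c, ps in by_chrom.items():
        if known and c not in known:
            warnings.warn(f"chromosome {c!r} absent from mask; "
                          f"{len(ps)} positions dropped")
            continue
        ps = np.asarray(sorted(ps), dtype=np.int64)
        keep = ps[~mask.is_masked(c, ps)]
        out.update((c, int(p)) for p in keep)
    return out


# ---------------------------------------------------------------------------
# MultiAlignment

_BASES = "ACGT"
BASE_TO_CODE = {b: i for i, b in enumerate(_BASES)}
BASE_TO_CODE.update({"-": 4, "N": 5})
CODE_TO_BASE = np.array(list(_BASES + "-N"))


@dataclass
class MultiAlignment:
    """Reference-projected multiple alignment on one chromosome.

    ``codes`` is a (n_species, length) uint8 matrix with A,C,G,T,-,N coded
    0..5.  The reference row never contains the gap code.
    """

    species: list
    codes: np.ndarray
    refspecies: str
    chrom: str = "chr"
    start: int = 0

    def __post_init__(self):
        if self.refspecies not in self.species:
            raise ValueError(f"refspecies {self.refspecies!r} not among species")
        ref = self.codes[self.species.index(self.refspecies)]
        if (ref == 4).any():
            raise ValueError("reference row contains gaps after projection")

    @property
    def length(self):
        return self.codes.shape[1]

    def row(self, name) -> np.ndarray:
        return self.codes[self.species.index(name)]

    def ref_row(self) -> np.ndarray:
        return self.row(self.refspecies)

    def seq(self, name) -> str:
        return "".join(CODE_TO_BASE[self.row(name)])

    @classmethod
    def from_seqs(cls, seqs: dict, refspecies: str, chrom="chr", start=0):
        species = list(seqs)
        codes = np.vstack([encode_seq(seqs[s]) for s in species])
        return cls(species, codes, refspecies, chrom, start)


def encode_seq(seq) -> np.ndarray:
    arr = np.frombuffer(str(seq).upper().encode(), dtype=np.uint8)
    out = np.full(arr.shape, 5, dtype=np.uint8)
    for base, code in BASE_TO_CODE.items():
        out[arr == ord(base)] = code
    return out


def decode_seq(codes) -> str:
    return "".join(CODE_TO_BASE[np.asarray(codes)])


def read_alignment(path, refspecies) -> MultiAlignment:
    """Read a MAF file and project it onto the reference coordinate system.

    Blocks must be non-overlapping on the reference.  Columns where the
    reference is gapped (insertions in other species) are dropped; species
    missing from a block are filled with N; positions between blocks are N
    for every non-reference species and N for the reference as well (no
    sequence information there).
    """
    blocks = []
    for msa in AlignIO.parse(str(path), "maf"):
        # MAF ids are species.chrom; key blocks by the species part
        recs = {rec.id.split(".")[0]: rec for rec in msa}
        if refspecies not in recs:
            raise ValueError(f"refspecies {refspecies!r} missing from a MAF block")
        blocks.append((recs[refspecies].annotations["start"], recs))
    if not blocks:
        raise ValueError("no alignment blocks found")
    blocks.sort(key=lambda b: b[0])
    species = [refspecies] + sorted(
        {s for _, recs in blocks for s in recs} - {refspecies})
    chrom = None
    projected = []
    prev_end = None
    for rstart, recs in blocks:
        ref = recs[refspecies]
        if chrom is None and "." in ref.id:
            chrom = ref.id.split(".", 1)[1]
        mat = np.vstack([
            encode_seq(str(recs[s].seq)) if s in recs
            else np.full(len(ref.seq), 5, dtype=np.uint8)
            for s in species])
        keep = mat[0] != 4  # drop reference-gap columns
        mat = mat[:, keep]
        rend = rstart + mat.shape[1]
        if prev_end is not None and rstart < prev_end:
            raise ValueError(
                f"overlapping MAF blocks on reference: block at {rstart} "
                f"begins before previous end {prev_end}")
        if prev_end is not None and rstart > prev_end:
            gap = np.full((len(species), rstart - prev_end), 5, dtype=np.uint8)
            projected.append(gap)
        projected.append(mat)
        prev_end = rend
    codes = np.hstack(projected)
    return MultiAlignment(species, codes, refspecies,
                          chrom=chrom or "chr", start=blocks[0][0])


def write_alignment(aln: MultiAlignment, path):
    """Write one MAF block per contiguous reference stretch."""
    ref = aln.ref_row()
    informative = ref != 5
    # contiguous runs of informative reference positions
    edges = np.flatnonzero(np.diff(np.concatenate(
        ([0], informative.view(np.int8), [0]))))
    msas = []
    for i in range(0, len(edges), 2):
        s, e = edges[i], edges[i + 1]
        records = []
        for sp in aln.species:
            sub = aln.codes[aln.species.index(sp), s:e]
            text = decode_seq(sub)
            rec = SeqRecord(Seq(text), id=f"{sp}.{aln.chrom}")
            rec.annotations.update({
                "start": aln.start + s, "size": int((sub != 4).sum()),
                "strand": 1, "srcSize": aln.start + aln.length})
            records.append(rec)
        msas.append(MultipleSeqAlignment(records))
    with open(path, "w") as fh:
        AlignIO.write(msas, fh, "maf")


# ---------------------------------------------------------------------------
# FASTA / BED / bedGraph / signal tracks


def read_fasta(path) -> dict:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict, path):
    recs = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(recs, str(path), "fasta")


def read_bed(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    names = ["chrom", "start", "end", "name", "score", "strand"][: df.shape[1]]
    df.columns = names + list(df.columns[len(names):])
    return df


def write_bed(df: pd.DataFrame, path):
    df.to_csv(path, sep="\t", header=False, index=False)


@dataclass
class SignalTrackRaw:
    """Binned signal covering one chromosome with fixed 20 bp bins."""

    chrom: str
    binsize: int
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)

    @property
    def n_bins(self):
        return len(self.values)

    def per_bp(self, length=None) -> np.ndarray:
        """Expand bin values to per-bp resolution."""
        out = np.repeat(self.values, self.binsize)
        if length is not None:
            out = out[:length]
        return out


def read_bedgraph(path, binsize=20) -> dict:
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["chrom", "start", "end", "value"])
    tracks = {}
    for chrom, sub in df.groupby("chrom", sort=False):
        sub = sub.sort_values("start")
        if not ((sub.end - sub.start) == binsize).all():
            raise ValueError(f"bedGraph bins on {chrom} are not {binsize} bp")
        n = int(sub.end.max()) // binsize
        vals = np.zeros(n)
        vals[(sub.start // binsize).to_numpy()] = sub.value.to_numpy()
        tracks[chrom] = SignalTrackRaw(chrom, binsize, vals)
    return tracks


def write_bedgraph(track: SignalTrackRaw, path):
    starts = np.arange(track.n_bins) * track.binsize
    pd.DataFrame({
        "chrom": track.chrom, "start": starts,
        "end": starts + track.binsize, "value": track.values,
    }).to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# SNP tables


def read_snp_table(path) -> pd.DataFrame:
    """Read a SNP TSV (chrom, pos, allele1, allele2, freq1, coverage).

    Major/minor alleles are assigned by relative abundance; exact 50/50
    ties go to allele1 as major (documented tie rule).  Records violating
    frequency bounds or duplicating a position are fatal.  Multi-allelic
    records (allele fields longer than one base, or flagged via an
    optional ``n_alleles`` column) are retained here and removed later by
    :func:`cescape.snp_freq.filter_snps`.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"chrom", "pos", "allele1", "allele2", "freq1", "coverage"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"SNP table missing columns: {sorted(missing)}")
    if ((df.freq1 < 0) | (df.freq1 > 1)).any():
        raise ValueError("freq1 outside [0,1]")
    if df.duplicated(["chrom", "pos"]).any():
        dup = df[df.duplicated(["chrom", "pos"])].iloc[0]
        raise ValueError(f"duplicate SNP position {dup.chrom}:{dup.pos}")
    return snp_table_from_alleles(df)


def snp_table_from_alleles(df: pd.DataFrame) -> pd.DataFrame:
    major_is_1 = df.freq1 >= 0.5
    out = df.copy()
    out["major"] = np.where(major_is_1, df.allele1, df.allele2)
    out["minor"] = np.where(major_is_1, df.allele2, df.allele1)
    out["maf"] = np.where(major_is_1, 1 - df.freq1, df.freq1)
    if "n_alleles" not in out.columns:
        out["n_alleles"] = 2
    out = out.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    return out


def write_snp_table(df: pd.DataFrame, path):
    cols = ["chrom", "pos", "allele1", "allele2", "freq1", "coverage"]
    extra = [c for c in ("n_alleles",) if c in df.columns]
    df[cols + extra].to_csv(path, sep="\t", index=False)
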