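"""Rare-allele frequency stratification by mutation type and local GC.

SNPs are filtered (biallelic, minor-allele frequency above a noise floor,
adequate coverage, unmasked), typed by the GC effect and ti/tv class of
the major -> minor direction (major allele as the proxy ancestral state),
and binned by the G+C fraction of a small window around the site in the
reference sequence — optionally cross-stratified by a second, regional
scale.  The statistic per cell is the fraction of SNPs whose minor-allele
frequency falls below the rare cutoff, with binomial CIs.  Presets follow
the fly (20 bp x 20 bins, 200 bp x 5 bins, band 0.01-0.05) and mammalian
(20 bp x 5 bins, 1 kb x 5 bins, cutoff 0.082) analyses.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .genome_io import GenomeMask, encode_seq

PRESETS = {
    "fly": dict(local_scale=20, local_bins=20, regional_scale=200,
                regional_bins=5, rare_band=(0.01, 0.05)),
    "mammal": dict(local_scale=20, local_bins=5, regional_scale=1000,
                   regional_bins=5, rare_band=(0.0, 0.082)),
}

_TI = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
_GC = {"G", "C"}


def filter_snps(t: pd.DataFrame, min_maf: float = 0.01, min_cov: int = 10,
                mask: GenomeMask | None = None) -> pd.DataFrame:
    """Keep biallelic SNPs with maf > min_maf, coverage >= min_cov, and
    (when a mask is given) unmasked positions."""
    keep = (t["maf"] > min_maf) & (t["coverage"] >= min_cov)
    n_alleles = t["n_alleles"].fillna(2) if "n_alleles" in t.columns \
        else pd.Series(2, index=t.index)
    keep &= n_alleles == 2
    keep &= t["major"].isin(list("ACGT")) & t["minor"].isin(list("ACGT"))
    out = t[keep]
    if mask is not None:
        drop = np.zeros(len(out), dtype=bool)
        for chrom, sub in out.groupby("chrom"):
            drop[out.index.get_indexer(sub.index)] = mask.is_masked(
                chrom, sub["pos"].to_numpy())
        out = out[~drop]
    if out.empty:
        warnings.warn("no SNPs survive filtering")
    return out.reset_index(drop=True)


def classify_mutation(major: str, minor: str):
    """(gc_effect, titv) of the major -> minor direction."""
    if major == minor:
        raise ValueError("major and minor alleles are identical")
    if major not in "ACGT" or minor not in "ACGT":
        return None
    if major in _GC and minor not in _GC:
        effect = "loss"
    elif major not in _GC and minor in _GC:
        effect = "gain"
    else:
        effect = "neutral"
    titv = "transition" if (major, minor) in _TI else "transversion"
    return effect, titv


def classify_table(t: pd.DataFrame) -> pd.DataFrame:
    pairs = t["major"] + t["minor"]
    gc_eff = []
    titv = []
    for p in pairs:
        eff, tv = classify_mutation(p[0], p[1])
        gc_eff.append(eff)
        titv.append(tv)
    out = t.copy()
    out["gc_effect"] = gc_eff
    out["titv"] = titv
    out["mutation_type"] = out["gc_effect"] + "_" + out["titv"]
    return out


def local_gc(seq, pos, scale: int = 20, exclude_focal: bool = True):
    """G+C fraction in the scale-bp window centered on each position.

    The focal base is excluded by default (including it couples the bin
    to the allele identity mechanically); N bases never count toward the
    denominator, and a zero denominator yields NaN.
    """
    codes = seq if isinstance(seq, np.ndarray) else encode_seq(seq)
    pos = np.atleast_1d(np.asarray(pos, dtype=np.int64))
    L = len(codes)
    is_gc = np.isin(codes, (1, 2)).astype(np.int64)
    is_known = (codes < 4).astype(np.int64)
    cgc = np.concatenate(([0], np.cumsum(is_gc)))
    ckn = np.concatenate(([0], np.cumsum(is_known)))
    lo = np.maximum(pos - scale // 2, 0)
    hi = np.minimum(pos + (scale - scale // 2), L)
    gc = (cgc[hi] - cgc[lo]).astype(float)
    n = (ckn[hi] - ckn[lo]).astype(float)
    if exclude_focal:
        gc -= is_gc[pos]
        n -= is_known[pos]
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(n > 0, gc / n, np.nan)
    return out if out.size > 1 else float(out[0])


def rare_allele_spectrum(t: pd.DataFrame, seq, local_scale: int = 20,
                         local_bins: int = 20, regional_scale: int | None = None,
                         regional_bins: int = 5,
                         rare_band: tuple = (0.01, 0.05),
                         exclude_focal: bool = True,
                         binning: str = "width", min_n: int = 25,
                         preset: str | None = None) -> pd.DataFrame:
    """Long-format spectrum: per (mutation type, local-GC bin [, regional
    bin]) the rare-allele fraction f_rare = P(maf < hi), with binomial CI
    and a low_n flag below min_n records.  Bins are equal-width on [0,1]
    (binning="width") or equal-count quantiles (binning="quantile")."""
    if preset:
        p = PRESETS[preset]
        local_scale, local_bins = p["local_scale"], p["local_bins"]
        regional_scale, regional_bins = p["regional_scale"], p["regional_bins"]
        rare_band = p["rare_band"]
    codes = seq if isinstance(seq, np.ndarray) else encode_seq(seq)
    t = classify_table(t)
    pos = t["pos"].to_numpy()
    lg = local_gc(codes, pos, local_scale, exclude_focal)
    lg = np.atleast_1d(lg)
    ok = np.isfinite(lg)
    axes = {"local": (lg, local_bins)}
    if regional_scale:
        rg = np.atleast_1d(local_gc(codes, pos, regional_scale, exclude_focal))
        ok &= np.isfinite(rg)
        axes["regional"] = (rg, regional_bins)
    t = t[ok].reset_index(drop=True)
    edges = {}
    ids = {}
    for name, (v, nb) in axes.items():
        v = v[ok]
        if binning == "quantile":
            e = np.unique(np.quantile(v, np.linspace(0, 1, nb + 1)))
        else:
            e = np.linspace(0, 1, nb + 1)
        edges[name] = e
        ids[name] = np.clip(np.searchsorted(e, v, side="right") - 1,
                            0, len(e) - 2)
    lo_cut, hi_cut = rare_band
    rare = t["maf"].to_numpy() < hi_cut
    group_cols = {"mutation_type": t["mutation_type"].to_numpy(),
                  "gc_effect": t["gc_effect"].to_numpy()}
    df = pd.DataFrame({**group_cols, "rare": rare})
    for name in axes:
        df[f"{name}_bin"] = ids[name]
    keys = ["mutation_type", "gc_effect"] + [f"{n}_bin" for n in axes]
    agg = df.groupby(keys, observed=True)["rare"].agg(["sum", "count"]).reset_index()
    agg = agg.rename(columns={"sum": "n_rare", "count": "n"})
    p = agg["n_rare"] / agg["n"]
    half = 1.959964 * np.sqrt(p * (1 - p) / agg["n"])
    agg["f_rare"] = p
    agg["ci_lo"] = p - half
    agg["ci_hi"] = p + half
    agg["low_n"] = agg["n"] < min_n
    for name in axes:
        e = edges[name]
        agg[f"{name}_lo"] = e[agg[f"{name}_bin"]]
        agg[f"{name}_hi"] = e[agg[f"{name}_bin"] + 1]
    return agg
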