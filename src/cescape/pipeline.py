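"""End-to-end orchestration: simulate -> learn -> posteriors -> call CEs ->
profiles / clustering / compensation / SNP spectra / k-mer scan.

One YAML-able config drives a seeded, logged run; every stage writes its
outputs plus a manifest entry (parameters, output checksums), and
re-running the same config reproduces deterministic outputs bit-exactly.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import ce_caller, clustering, compensation, kmer_scan, profiles, snp_freq
from .genome_io import (write_alignment, write_bed, write_bedgraph,
                        write_fasta, write_snp_table)
from .phylo import Phylogeny
from .subst_model import divergence_track, infer_posteriors, learn_model
from .synthetic_data import (GCLandscape, SimConfig, SignalTrackRaw,
                             evolve_alignment, make_landscape, simulate_snps,
                             simulate_tracks, write_truth)

# deep enough that a neutral 20 bp window carries ~40 expected
# substitutions, so two-fold depletion is essentially never noise
DEFAULT_TREE = ("((A:0.18,B:0.20)ab:0.12,((C:0.17,D:0.15)cd:0.10,"
                "(E:0.16,F:0.18)ef:0.11)cdef:0.09,"
                "(G:0.26,H:0.28)gh:0.13)root;")


@dataclass
class RunConfig:
    seed: int = 0
    outdir: str = "run"
    newick: str = DEFAULT_TREE
    length: int = 200_000
    n_ces: int = 40
    kappa: float = 0.0
    rho: float = 0.25
    n_snps: int = 20_000
    window: int = 20
    ratio: float = 0.5
    expand: int = 10
    minlen: int = 30
    n_iter: int = 2
    tau: float = 0.9
    epi_k: int = 3
    seq_k: int = 20
    kmer_k: int = 6
    kmer_binwidth: int = 50
    profile_halfwidth: int = 1000
    stages: list = field(default_factory=lambda: [
        "simulate", "model", "callce", "profiles", "cluster",
        "compensate", "snpfreq", "kmer"])

    @classmethod
    def from_yaml(cls, path):
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def to_yaml(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh)


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(cfg: RunConfig) -> Path:
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(out / "config.yaml")
    manifest = {}
    state: dict = {}

    def record(stage, t0, files, params=None):
        manifest[stage] = {
            "seconds": round(time.time() - t0, 2),
            "params": params or {},
            "outputs": {f.name: _checksum(f) for f in files},
        }

    for stage in cfg.stages:
        t0 = time.time()
        files = _STAGES[stage](cfg, state, out)
        record(stage, t0, files)
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1)
    return out


def _need(state, key, stage):
    if key not in state:
        raise RuntimeError(f"stage {stage!r} requires upstream artifact {key!r}")
    return state[key]


def _stage_simulate(cfg, state, out):
    tree = Phylogeny.from_newick(cfg.newick)
    sim = SimConfig(tree=tree, length=cfg.length, kappa=cfg.kappa,
                    rho=cfg.rho, seed=cfg.seed)
    landscape = make_landscape(sim, cfg.n_ces)
    aln, log, root = evolve_alignment(landscape, sim)
    snps = simulate_snps(landscape, aln.ref_row(), cfg.n_snps, sim)
    tracks, truth = simulate_tracks(landscape, aln.ref_row(), sim)
    state.update(sim=sim, landscape=landscape, aln=aln, log=log,
                 snps=snps, tracks=tracks, track_truth=truth, tree=tree)
    write_fasta({s: aln.seq(s) for s in aln.species}, out / "leaves.fa")
    write_alignment(aln, out / "alignment.maf")
    write_bed_df = [(aln.chrom, s, e, f"core{i}", 0, ".")
                    for i, (s, e) in enumerate(landscape.ce_truth)]
    write_bed(pd.DataFrame(write_bed_df), out / "ce_truth.bed")
    write_snp_table(snps, out / "snps.tsv")
    for name, tr in tracks.items():
        write_bedgraph(tr, out / f"track_{name}.bedgraph")
    write_truth(out / "truth.json", landscape, log, extra=truth)
    write_bedgraph(SignalTrackRaw(aln.chrom, 1, landscape.target_gc),
                   out / "target_gc.bedgraph")
    return [out / "leaves.fa", out / "alignment.maf", out / "ce_truth.bed",
            out / "snps.tsv", out / "truth.json"]


def _stage_model(cfg, state, out):
    aln = _need(state, "aln", "model")
    tree = state["tree"]
    model = learn_model(aln, tree, n_iter=cfg.n_iter)
    post = infer_posteriors(aln, tree, model)
    div = divergence_track(post, model, chrom=aln.chrom)
    state.update(model=model, post=post, div=div)
    model.to_json(out / "model.json")
    write_bedgraph(SignalTrackRaw(aln.chrom, 1, div.obs), out / "obs.bedgraph")
    write_bedgraph(SignalTrackRaw(aln.chrom, 1, div.exp), out / "exp.bedgraph")
    return [out / "model.json", out / "obs.bedgraph", out / "exp.bedgraph"]


def _stage_callce(cfg, state, out):
    div = _need(state, "div", "callce")
    ces = ce_caller.call_ces(div, cfg.window, cfg.ratio, cfg.expand, cfg.minlen)
    state["ces"] = ces
    write_bed(ce_caller.ces_to_bed(ces), out / "ces.bed")
    return [out / "ces.bed"]


def _stage_profiles(cfg, state, out):
    aln = _need(state, "aln", "profiles")
    ces = _need(state, "ces", "profiles")
    centers = [c.center for c in ces]
    files = []
    if centers:
        prof = profiles.composition_profile(
            aln.ref_row(), centers, halfwidth=cfg.profile_halfwidth)
        prof.to_frame().to_csv(out / "composition_profile.tsv",
                               sep="\t", index=False)
        files.append(out / "composition_profile.tsv")
        div = state["div"]
        for label, vals in (("obs", div.obs), ("exp", div.exp)):
            sp = profiles.signal_profile(vals, centers,
                                         halfwidth=cfg.profile_halfwidth,
                                         binwidth=20, valid=div.valid)
            sp.to_frame().to_csv(out / f"{label}_profile.tsv", sep="\t",
                                 index=False)
            files.append(out / f"{label}_profile.tsv")
    return files


def _stage_cluster(cfg, state, out):
    ces = _need(state, "ces", "cluster")
    tracks = _need(state, "tracks", "cluster")
    norm = {n: profiles.normalize_track(t) for n, t in tracks.items()
            if n.startswith("mark")}
    X, kept, names = clustering.epi_feature_matrix(ces, norm)
    files = []
    if len(X) > cfg.epi_k:
        assign = clustering.kmeans_cluster(X, cfg.epi_k, seed=cfg.seed)
        pd.DataFrame({"ce": kept, "cluster": assign.labels}).to_csv(
            out / "epi_clusters.tsv", sep="\t", index=False)
        files.append(out / "epi_clusters.tsv")
        state["epi_assign"] = assign
        state["epi_kept"] = kept
    vecs, kept2 = clustering.dinuc_gc_encode(state["aln"].ref_row(), ces)
    if len(vecs) > cfg.seq_k:
        sa = clustering.kmeans_cluster(vecs.astype(float), cfg.seq_k,
                                       seed=cfg.seed)
        pd.DataFrame({"ce": kept2, "cluster": sa.labels}).to_csv(
            out / "seq_clusters.tsv", sep="\t", index=False)
        files.append(out / "seq_clusters.tsv")
    return files


def _stage_compensate(cfg, state, out):
    aln = _need(state, "aln", "compensate")
    sp1, sp2 = aln.species[:2]
    track = compensation.gc_delta(aln, sp1, sp2)
    distances = list(range(1, 41)) + [60, 100, 200, 500]
    curve = compensation.coupling_curve(track, distances)
    curve.to_frame().to_csv(out / "coupling.tsv", sep="\t", index=False)
    files = [out / "coupling.tsv"]
    if "post" in state and "ces" in state:
        bal = compensation.rate_balance_profile(
            state["post"], state["model"], state["ces"],
            halfwidth=cfg.profile_halfwidth)
        bal.to_csv(out / "balance.tsv", sep="\t", index=False)
        files.append(out / "balance.tsv")
    state["coupling"] = curve
    return files


def _stage_snpfreq(cfg, state, out):
    snps = _need(state, "snps", "snpfreq")
    aln = state["aln"]
    kept = snp_freq.filter_snps(snps)
    spec = snp_freq.rare_allele_spectrum(kept, aln.ref_row(), preset="fly")
    spec.to_csv(out / "snp_spectrum.tsv", sep="\t", index=False)
    state["snp_spectrum"] = spec
    return [out / "snp_spectrum.tsv"]


def _stage_kmer(cfg, state, out):
    aln = _need(state, "aln", "kmer")
    ces = _need(state, "ces", "kmer")
    if not ces:
        return []
    freq, n_starts, comp, offsets = kmer_scan.kmer_distance_freq(
        aln.ref_row(), ces, cfg.kmer_k, cfg.kmer_binwidth,
        cfg.profile_halfwidth)
    repeats = ["CACACA", "TATATA", "CAACAA", "AAAAAA"]
    enr = kmer_scan.normalized_enrichment(freq, n_starts, comp, cfg.kmer_k,
                                          kmers=repeats)
    enr.to_csv(out / "kmer_enrichment.tsv", sep="\t", index=False)
    return [out / "kmer_enrichment.tsv"]


_STAGES = {
    "simulate": _stage_simulate,
    "model": _stage_model,
    "callce": _stage_callce,
    "profiles": _stage_profiles,
    "cluster": _stage_cluster,
    "compensate": _stage_compensate,
    "snpfreq": _stage_snpfreq,
    "kmer": _stage_kmer,
}
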