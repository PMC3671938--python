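"""Pre-configured synthetic study designs and their summary statistics.

Each function runs one self-contained experiment — simulate under known
conditions, run the analysis pipeline, score the result against the
recorded ground truth — and returns a dict of summary numbers.  They are
the package's reference experiments: the test suite asserts on their
outputs and the reproduction script reports them.

Design notes on the fixed study conditions:

* The parameter-recovery study uses a 5-taxon star phylogeny: every
  branch's parent is the root, which four other lineages corroborate, so
  ancestral states (and hence per-branch context-specific counts) are
  close to fully identified.  On trees with internal branches the same
  estimator is confounded by ancestor-attribution uncertainty, which is a
  property of the design, not of the estimator being validated.
* The conserved-element study uses an 8-taxon tree with total length
  ~2.1 substitutions/site so that a neutral 20 bp window carries ~40
  expected substitutions — enough that two-fold depletion is essentially
  never reached by chance.
* The polymorphism study uses the smooth two-scale GC landscape and a
  reference sequence at mutation-selection balance (see
  synthetic_data.balance_sequence); sharp core boundaries would place
  window/target mismatches exactly where SNPs are densest.
"""

from __future__ import annotations

from itertools import product

import numpy as np
from scipy.stats import spearmanr

from . import ce_caller
from .compensation import (conditional_rate_test, coupling_curve, gc_delta,
                           lineage_events, permutation_flatness)
from .genome_io import MultiAlignment
from .kmer_scan import kmer_bin_frequencies, normalized_enrichment
from .phylo import Phylogeny
from .profiles import composition_profile, normalize_track
from .snp_freq import classify_table, filter_snps, local_gc, rare_allele_spectrum
from .subst_model import (SubstModel, divergence_track, infer_posteriors,
                          learn_model)
from .synthetic_data import (SimConfig, balance_sequence, evolve_alignment,
                             make_landscape, make_smooth_landscape,
                             sample_root, simulate_snps, simulate_tracks,
                             substream)

STAR5 = "(A:0.12,B:0.14,C:0.12,D:0.10,E:0.20)root;"
TREE4 = "((A:0.1,B:0.12)ab:0.05,(C:0.1,D:0.08)cd:0.06)root;"
TREE8 = ("((A:0.18,B:0.20)ab:0.12,((C:0.17,D:0.15)cd:0.10,"
         "(E:0.16,F:0.18)ef:0.11)cdef:0.09,(G:0.26,H:0.28)gh:0.13)root;")
TREE2 = "(mel:0.25,yak:0.25)root;"
TREE3 = "(mel:0.2,yak:0.2,out:0.35)root;"

CPG_MULT = np.ones((4, 4))
CPG_MULT[1, 2] = 2.5          # focal G after C: hypermutable context


def _seed(seed: int, k: int) -> int:
    return (seed * 1009 + k) % (2 ** 31)


# ---------------------------------------------------------------------------
# Ancestral-inference oracle


def exhaustive_posteriors(aln, tree, model, ctx, root_ctx):
    """Brute-force reference: sum over every joint ancestral assignment.

    Independent of the pruning implementation; cost 4^(#hidden nodes) per
    position, so only usable on tiny trees.
    """
    hidden = [i for i in range(tree.n_nodes)
              if tree.names[i] not in aln.species]
    bidx = {tree.names[n]: k for k, n in enumerate(tree.branch_nodes())}
    L = aln.length
    J = {b: np.zeros((L, 4, 4)) for b in bidx}
    marg = {tree.names[i]: np.zeros((L, 4)) for i in range(tree.n_nodes)}
    for l in range(L):
        for assign in product(range(4), repeat=len(hidden)):
            state = {}
            for i in range(tree.n_nodes):
                name = tree.names[i]
                if name in aln.species:
                    state[i] = int(aln.row(name)[l])
                else:
                    state[i] = assign[hidden.index(i)]
            p = model.root_prior[root_ctx[l], state[tree.root]] \
                if state[tree.root] < 4 else 0.0
            contribs = {}
            for node in tree.branch_nodes():
                name = tree.names[node]
                k = bidx[name]
                x = state[tree.parent[node]]
                y = state[node]
                if y >= 4:          # ambiguous observed leaf: marginalize
                    row = model.P[k, ctx[k, l], x]
                    contribs[name] = ("row", x, row)
                else:
                    p *= model.P[k, ctx[k, l], x, y]
            if p == 0:
                continue
            for node in tree.branch_nodes():
                name = tree.names[node]
                k2 = bidx[name]
                x = state[tree.parent[node]]
                y = state[node]
                if name in contribs:
                    J[name][l, x] += p * contribs[name][2]
                else:
                    J[name][l, x, y] += p
            for i in range(tree.n_nodes):
                if state[i] < 4:
                    marg[tree.names[i]][l, state[i]] += p
    for b in J:
        J[b] /= J[b].sum(axis=(1, 2), keepdims=True)
    for n in marg:
        tot = marg[n].sum(axis=1, keepdims=True)
        marg[n] = np.divide(marg[n], tot, out=np.zeros_like(marg[n]),
                            where=tot > 0)
    return J, marg


def ancestral_oracle_study(seed: int, L: int = 200) -> dict:
    """Pruning posteriors vs exhaustive enumeration on a 4-taxon tree."""
    rng = np.random.default_rng(_seed(seed, 1))
    tree = Phylogeny.from_newick(TREE4)
    codes = rng.integers(0, 4, size=(4, L)).astype(np.uint8)
    codes[1, : L // 10] = 5
    aln = MultiAlignment(["A", "B", "C", "D"], codes, "A")
    branches = [tree.names[i] for i in tree.branch_nodes()]
    P = rng.random((len(branches), 17, 4, 4)) + np.eye(4) * 3
    P /= P.sum(axis=3, keepdims=True)
    prior = rng.random((17, 4)) + 1
    prior /= prior.sum(axis=1, keepdims=True)
    model = SubstModel(branches, P, prior)
    post = infer_posteriors(aln, tree, model)
    from .subst_model import context_ids
    rctx = context_ids(aln.ref_row())
    J_bf, marg_bf = exhaustive_posteriors(aln, tree, model, post.ctx, rctx)
    err = 0.0
    for b, Jb in J_bf.items():
        err = max(err, np.abs(Jb - post.J[post.branch_index(b)]).max())
    for n, m in marg_bf.items():
        if n in aln.species:       # ambiguous observed rows are not tallied
            continue
        err = max(err, np.abs(m - post.node_marginals[n]).max())
    return {"max_abs_error": float(err), "n": L}


# ---------------------------------------------------------------------------
# Model parameter recovery


def model_recovery_study(seed: int, length: int = 200_000,
                         n_iter: int = 4, min_events: int = 200) -> dict:
    tree = Phylogeny.from_newick(STAR5)
    cfg = SimConfig(tree=tree, length=length, kappa=0.0, rho=1.0,
                    seed=_seed(seed, 2), context_multipliers=CPG_MULT)
    ls = make_landscape(cfg, 0)
    aln, log, root = evolve_alignment(ls, cfg, burn_in=4.0)
    seqs = log.replay(tree, root)
    seqs[tree.names[tree.root]] = root
    model = learn_model(aln, tree, n_iter=n_iter)
    rel = []
    for bi, name in enumerate(model.branches):
        node = tree.names.index(name)
        pseq = seqs[tree.names[tree.parent[node]]]
        cseq = seqs[name]
        for k in range(16):
            sel = np.zeros(len(pseq), bool)
            sel[1:-1] = (pseq[:-2] == k // 4) & (pseq[2:] == k % 4)
            px, cy = pseq[sel], cseq[sel]
            for x in range(4):
                m = px == x
                for y in range(4):
                    if x == y:
                        continue
                    n_ev = int((cy[m] == y).sum())
                    if n_ev >= min_events:
                        rel.append(abs(model.P[bi, k, x, y]
                                       / (n_ev / m.sum()) - 1))
    rel = np.array(rel)
    post = infer_posteriors(aln, tree, model)
    div = divergence_track(post, model)
    return {
        "n_cells": int(len(rel)),
        "max_rel_error": float(rel.max()),
        "frac_within_15pct": float((rel <= 0.15).mean()),
        "obs_exp_ratio": float(div.obs.sum() / div.exp.sum()),
        "n": length,
    }


# ---------------------------------------------------------------------------
# Conserved-element recovery


def ce_recovery_study(seed: int, length: int = 500_000,
                      n_cores: int = 100) -> dict:
    tree = Phylogeny.from_newick(TREE8)
    cfg = SimConfig(tree=tree, length=length, kappa=0.0, rho=0.25,
                    seed=_seed(seed, 3))
    ls = make_landscape(cfg, n_cores)
    aln, log, root = evolve_alignment(ls, cfg)
    model = learn_model(aln, tree, n_iter=2)
    post = infer_posteriors(aln, tree, model)
    div = divergence_track(post, model, chrom="chrS")
    ces = ce_caller.call_ces(div)
    sens, false_frac, _ = ce_caller.match_to_truth(ces, ls.ce_truth)
    prof = composition_profile(aln.ref_row(), [c.center for c in ces],
                               halfwidth=600)
    gc = prof.value[:, 1] + prof.value[:, 2]
    off = prof.offsets
    center_gc = float(gc[np.abs(off) <= 5].mean())
    flank_band = gc[(np.abs(off) >= 20) & (np.abs(off) <= 80)]
    far_gc = float(np.nanmean(gc[np.abs(off) >= 500]))
    return {
        "n_called": len(ces),
        "sensitivity": float(sens),
        "false_call_fraction": float(false_frac),
        "profile_center_gc": center_gc,
        "profile_flank_max_gc": float(np.nanmax(flank_band)),
        "profile_argmin_abs_offset": int(abs(off[np.nanargmin(gc)])),
        "profile_background_gc": far_gc,
        "obs_exp_ratio": float(div.obs.sum() / div.exp.sum()),
        "n": length,
    }


# ---------------------------------------------------------------------------
# Compensation


def compensation_study(seed: int, length: int = 200_000,
                       kappa: float = 10.0) -> dict:
    tree2 = Phylogeny.from_newick(TREE2)
    cfg0 = SimConfig(tree=tree2, length=length, kappa=0.0,
                     seed=_seed(seed, 4))
    ls = make_landscape(cfg0, 0)
    aln0, _, _ = evolve_alignment(ls, cfg0, burn_in=2.0)
    track0 = gc_delta(aln0, "mel", "yak")
    null_frac = permutation_flatness(track0, np.arange(1, 41), n_perm=50,
                                     seed=_seed(seed, 40))

    cfg1 = SimConfig(tree=tree2, length=length, kappa=kappa,
                     seed=_seed(seed, 4))
    aln1, _, _ = evolve_alignment(ls, cfg1, burn_in=2.0)
    track1 = gc_delta(aln1, "mel", "yak")

    def pooled(track, dlist):
        c = coupling_curve(track, dlist)
        k = float(np.nansum(c.score * c.n_pairs))
        n = int(c.n_pairs.sum())
        p = k / n
        half = 1.959964 * np.sqrt(p * (1 - p) / n) + 0.5 / n
        return p, p - half, p + half, n

    s_p, s_lo, s_hi, s_n = pooled(track1, list(range(1, 21)))
    l_p, l_lo, l_hi, l_n = pooled(track1, [500])

    tree3 = Phylogeny.from_newick(TREE3)
    cfg3 = SimConfig(tree=tree3, length=length, kappa=kappa,
                     seed=_seed(seed, 5))
    ls3 = make_landscape(cfg3, 0)
    aln3, log3, root3 = evolve_alignment(ls3, cfg3, burn_in=2.0)
    model = learn_model(aln3, tree3, n_iter=2)
    post = infer_posteriors(aln3, tree3, model)
    gain, loss = lineage_events(post, "yak", tau=0.9)
    rates = conditional_rate_test(gain, loss, [5, 10, 20, 1000], cfg3.length)
    short = rates[rates.d <= 20]
    return {
        "null_outside_ci_fraction": float(null_frac),
        "coupling_short": s_p, "coupling_short_ci": (s_lo, s_hi),
        "coupling_long": l_p, "coupling_long_ci": (l_lo, l_hi),
        "n_pairs_short": s_n, "n_pairs_long": l_n,
        "min_opposite_same_ratio_short": float(
            np.nanmin(np.concatenate([short.gain_ratio, short.loss_ratio]))),
        "ratio_at_1kb": float(rates[rates.d == 1000].gain_ratio.iloc[0]),
        "n": length,
    }


# ---------------------------------------------------------------------------
# SNP rare-allele trends


def snp_study(seed: int, n_snps: int = 50_000, length: int = 300_000,
              kappa: float = 10.0) -> dict:
    tree = Phylogeny.from_newick("(x:0.1)root;")
    out = {}
    for label, k in (("null", 0.0), ("selected", kappa)):
        cfg = SimConfig(tree=tree, length=length, kappa=k,
                        seed=_seed(seed, 6))
        ls = make_smooth_landscape(cfg)
        ref = balance_sequence(ls, cfg)
        t = classify_table(filter_snps(simulate_snps(ls, ref, n_snps, cfg)))
        lg = local_gc(ref, t["pos"].to_numpy(), 20)
        rare = (t["maf"] < 0.05).to_numpy()
        rhos = {}
        for mt, sub in t.groupby("mutation_type"):
            idx = t.index.get_indexer(sub.index)
            rhos[mt], _ = spearmanr(lg[idx], rare[idx])
        out[label] = rhos
        if label == "selected":
            spec = rare_allele_spectrum(t, ref, local_scale=20,
                                        local_bins=20, regional_scale=200,
                                        regional_bins=5)
            strat = {}
            for eff in ("gain", "loss"):
                sub = spec[spec.gc_effect == eff]
                for rb, g in sub.groupby("regional_bin"):
                    agg = g.groupby("local_bin").agg(
                        nr=("n_rare", "sum"), n=("n", "sum")).reset_index()
                    agg = agg[agg.n >= 150]
                    if len(agg) >= 4:
                        rho, _ = spearmanr(agg.local_bin, agg.nr / agg.n)
                        strat[f"{eff}_regional_{rb}"] = float(rho)
            out["stratified"] = strat
    out["n"] = n_snps
    return out


# ---------------------------------------------------------------------------
# k-mer normalization null


def kmer_null_study(seed: int, per_bin: int = 10_000_000,
                    n_bins: int = 6) -> dict:
    rng = np.random.default_rng(_seed(seed, 7))
    gcs = np.linspace(0.32, 0.62, n_bins)
    seqs = []
    for gc in gcs:
        p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
        seqs.append(rng.choice(4, size=per_bin, p=p).astype(np.uint8))
    worst = 0.0
    for k, kmers in ((4, ["CACA", "TATA", "AAAA"]), (3, ["CAA"])):
        freq, n_starts, comp = kmer_bin_frequencies(seqs, k)
        enr = normalized_enrichment(freq, n_starts, comp, k, kmers=kmers)
        worst = max(worst, float(enr.norm_log2.abs().max()))
    freq6, n6, comp6 = kmer_bin_frequencies(seqs, 6)
    enr6 = normalized_enrichment(freq6, n6, comp6, 6, kmers=["CACACA"])
    elevated = [b for b in range(n_bins) if 0.45 <= gcs[b] <= 0.60]
    raw_ca3 = float(enr6[enr6.bin.isin(elevated)].raw_log2.min())
    return {"max_abs_norm_log2": worst,
            "raw_log2_ca3_elevated_min": raw_ca3,
            "n": per_bin * n_bins}


# ---------------------------------------------------------------------------
# Epigenetic clustering recovery


def clustering_study(seed: int, length: int = 200_000,
                     n_cores: int = 120) -> dict:
    from sklearn.metrics import adjusted_rand_score
    from .ce_caller import ConservedElement
    from .clustering import epi_feature_matrix, kmeans_cluster
    tree = Phylogeny.from_newick("(x:0.1)root;")
    cfg = SimConfig(tree=tree, length=length, seed=_seed(seed, 8))
    ls = make_landscape(cfg, n_cores)
    ref = sample_root(ls, substream(cfg.seed, "root"))
    tracks, truth = simulate_tracks(ls, ref, cfg)
    norm = {n: normalize_track(t) for n, t in tracks.items()
            if n.startswith("mark")}
    ces = [ConservedElement("chrS", s, e, 0.2) for s, e in ls.ce_truth]
    X, kept, _ = epi_feature_matrix(ces, norm)
    a = kmeans_cluster(X, 3, seed=_seed(seed, 9))
    b = kmeans_cluster(X, 3, seed=_seed(seed, 9))
    ari = adjusted_rand_score(np.array(truth["core_subsets"])[kept], a.labels)
    return {"adjusted_rand": float(ari),
            "deterministic": bool((a.labels == b.labels).all()),
            "n": n_cores}
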