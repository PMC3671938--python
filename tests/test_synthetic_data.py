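import numpy as np
import pytest
from scipy.stats import chi2_contingency

from cescape.phylo import Phylogeny
from cescape.snp_freq import filter_snps, local_gc
from cescape.synthetic_data import (SimConfig, balance_sequence,
                                    evolve_alignment, local_gc20,
                                    make_landscape, make_smooth_landscape,
                                    sample_root, simulate_snps,
                                    simulate_tracks, substream)


class TestLandscape:
    def test_no_cores_constant_background(self, tree4):
        cfg = SimConfig(tree=tree4, length=5000)
        ls = make_landscape(cfg, 0)
        assert (ls.target_gc == cfg.background_gc).all()

    def test_profile_shape(self, tree4):
        cfg = SimConfig(tree=tree4, length=20_000, core_gc=0.25,
                        flank_gc=0.55, background_gc=0.40)
        ls = make_landscape(cfg, 5)
        s, e = ls.ce_truth[0]
        center = (s + e) // 2
        win = ls.target_gc[center - 400: center + 400]
        assert win.min() == pytest.approx(0.25)
        assert win.max() == pytest.approx(0.55)
        # minimum at the core, maximum in the flank, background at the edge
        assert abs(np.argmin(win) - 400) <= (e - s)
        assert ls.target_gc[s - ls.flank_halfwidth - 1] == pytest.approx(0.40)

    def test_mean_core_target(self, tree4):
        cfg = SimConfig(tree=tree4, length=100_000)
        ls = make_landscape(cfg, 100, spacing="even")
        core = ls.target_gc[ls.core_mask()]
        assert abs(core.mean() - cfg.core_gc) < 0.01

    def test_infeasible_packing_fatal(self, tree4):
        cfg = SimConfig(tree=tree4, length=5000)
        with pytest.raises(ValueError, match="pack"):
            make_landscape(cfg, 50)

    def test_cores_separated(self, tree4):
        cfg = SimConfig(tree=tree4, length=100_000)
        ls = make_landscape(cfg, 50)
        for (s1, e1), (s2, e2) in zip(ls.ce_truth, ls.ce_truth[1:]):
            assert s2 - e1 >= 2 * cfg.flank_halfwidth


class TestEvolve:
    def test_replay_reproduces_leaves(self, small_sim):
        cfg, ls, aln, log, root = small_sim
        seqs = log.replay(cfg.tree, root)
        for name in aln.species:
            assert (seqs[name] == aln.row(name)).all()

    def test_neutral_rate_calibration(self, small_sim):
        """Realized per-branch substitution counts match the mutation-matrix
        expectation within 3 sigma (Poisson)."""
        cfg, ls, aln, log, root = small_sim
        tree = cfg.tree
        seqs = log.replay(tree, root)
        seqs[tree.names[tree.root]] = root
        Q = cfg.mutation_matrix
        row_tot = (Q - np.diag(np.diag(Q))).sum(axis=1)
        for node in tree.preorder():
            if node == tree.root:
                continue
            parent = seqs[tree.names[tree.parent[node]]]
            expected = float(tree.lengths[node]) * row_tot[
                parent.astype(int)].sum()
            observed = len(log.by_branch(tree.names[node]))
            assert abs(observed - expected) < 3 * np.sqrt(expected)

    def test_core_rate_suppression(self, tree4):
        """rho = 0.25 suppresses within-core substitution density ~4x."""
        cfg = SimConfig(tree=tree4, length=150_000, rho=0.25, seed=5)
        ls = make_landscape(cfg, 150)
        aln, log, root = evolve_alignment(ls, cfg)
        core = ls.core_mask()
        pos = np.array([p for _, p, _, _ in log.events])
        dens_in = core[pos].sum() / core.sum()
        dens_out = (~core[pos]).sum() / (~core).sum()
        assert abs(dens_in / dens_out - 0.25) < 0.05

    def test_selection_tracks_target(self, tree4):
        """With kappa > 0 the stationary local GC stays closer to the target
        profile than under neutral evolution (same landscape)."""
        tree = Phylogeny.from_newick("(A:0.3)root;")
        devs = {}
        for kappa in (0.0, 8.0):
            cfg = SimConfig(tree=tree, length=60_000, kappa=kappa, seed=5)
            ls = make_landscape(cfg, 12)
            aln, _, _ = evolve_alignment(ls, cfg, burn_in=2.0)
            g = local_gc20(aln.row("A"), np.arange(cfg.length))
            devs[kappa] = np.abs(g - ls.target_gc).mean()
        assert devs[8.0] < devs[0.0]

    def test_determinism(self, tree4):
        cfg = SimConfig(tree=tree4, length=20_000, kappa=5.0, seed=9)
        ls = make_landscape(cfg, 5)
        a1, l1, r1 = evolve_alignment(ls, cfg)
        a2, l2, r2 = evolve_alignment(ls, cfg)
        assert (a1.codes == a2.codes).all()
        assert l1.events == l2.events


class TestSnps:
    def test_null_spectrum_flat(self, tree4):
        """kappa = 0: rare-allele fraction homogeneous across local-GC bins."""
        cfg = SimConfig(tree=tree4, length=200_000, kappa=0.0, seed=2)
        ls = make_smooth_landscape(cfg)
        ref = balance_sequence(ls, cfg)
        t = filter_snps(simulate_snps(ls, ref, 50_000, cfg))
        lg = local_gc(ref, t["pos"].to_numpy(), 20)
        bins = np.clip((lg * 10).astype(int), 2, 7)
        rare = (t["maf"] < 0.05).to_numpy()
        table = np.array([[np.sum(rare[bins == b]), np.sum(~rare[bins == b])]
                          for b in np.unique(bins)])
        _, p, _, _ = chi2_contingency(table)
        assert p > 0.01

    def test_selected_panel_plants_loss_trend(self, tree4):
        """kappa > 0: GC-losing SNPs get rarer with local GC."""
        from scipy.stats import spearmanr
        from cescape.snp_freq import classify_table
        cfg = SimConfig(tree=tree4, length=200_000, kappa=10.0, seed=2)
        ls = make_smooth_landscape(cfg)
        ref = balance_sequence(ls, cfg)
        t = classify_table(filter_snps(simulate_snps(ls, ref, 50_000, cfg)))
        lg = local_gc(ref, t["pos"].to_numpy(), 20)
        loss = t.gc_effect == "loss"
        rho, _ = spearmanr(lg[loss], (t["maf"] < 0.05)[loss])
        assert rho > 0.1

    def test_low_coverage_all_filtered(self, tree4):
        cfg = SimConfig(tree=tree4, length=50_000, seed=1)
        ls = make_landscape(cfg, 5)
        ref = sample_root(ls, substream(1, "r"))
        snps = simulate_snps(ls, ref, 1000, cfg, coverage=5)
        assert len(filter_snps(snps)) == 0

    def test_too_many_snps_fatal(self, tree4):
        cfg = SimConfig(tree=tree4, length=5_000, seed=1)
        ls = make_landscape(cfg, 0)
        ref = sample_root(ls, substream(1, "r"))
        with pytest.raises(ValueError, match="available"):
            simulate_snps(ls, ref, 10_000, cfg)


class TestTracks:
    def test_nucleosome_monotone_in_gc(self, tree4):
        cfg = SimConfig(tree=tree4, length=50_000, seed=1)
        ls = make_landscape(cfg, 10)
        ref = sample_root(ls, substream(1, "r"))
        tracks, _ = simulate_tracks(ls, ref, cfg, nuc_noise=0.0)
        nuc = tracks["nucleosome"]
        gc_bin = np.isin(ref[: nuc.n_bins * 20].reshape(-1, 20),
                         (1, 2)).mean(axis=1)
        order = np.argsort(gc_bin)
        v = nuc.values[order]
        rising = np.diff(gc_bin[order]) > 0
        assert (np.diff(v)[rising] >= 0).all()

    def test_noise_limit_decorrelates(self, tree4):
        cfg = SimConfig(tree=tree4, length=100_000, seed=1)
        ls = make_landscape(cfg, 10)
        ref = sample_root(ls, substream(1, "r"))
        t_lo, _ = simulate_tracks(ls, ref, cfg, nuc_noise=0.01)
        t_hi, _ = simulate_tracks(ls, ref, cfg, nuc_noise=100.0)
        gc_bin = np.isin(ref[: t_lo["nucleosome"].n_bins * 20]
                         .reshape(-1, 20), (1, 2)).mean(axis=1)
        c_lo = np.corrcoef(t_lo["nucleosome"].values, gc_bin)[0, 1]
        c_hi = np.corrcoef(t_hi["nucleosome"].values, gc_bin)[0, 1]
        assert c_lo > 0.9 and abs(c_hi) < 0.1
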