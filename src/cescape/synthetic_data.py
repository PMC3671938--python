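"""Ground-truth generator: genomes with planted conserved elements, evolved
alignments, SNP panels and signal tracks.

The generator emulates the statistical structure the analysis pipeline is
built to detect: slow-evolving AT-rich cores (20-40 bp) embedded in
GC-elevated flanks, maintained by weak stabilizing selection on local
(20 bp) GC content; SNP allele-frequency spectra whose rare-allele mass
depends on the same selection coefficient; and binned signal tracks
correlated with local GC.  Every random draw comes from one seeded
generator with named substreams, and every substitution is logged so that
recovery can be scored against exact truth.

Substitutions follow origination-fixation dynamics: candidate mutations
arise one at a time along each branch (Poisson-thinned from a static
envelope), and each candidate with selection coefficient s = kappa * d,
where d is the decrease in |gc20 - target| caused by the mutation, fixes
with the diffusion probability (1 - e^(-2s)) / (1 - e^(-4Ns)), normalized
so that neutral candidates (s = 0) realize exactly the nominal rate.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit
from scipy.special import expit, logit

from .genome_io import MultiAlignment, SignalTrackRaw, encode_seq, snp_table_from_alleles
from .phylo import Phylogeny

GC_CODES = (1, 2)      # C, G in the ACGT coding


def substream(seed: int, label: str) -> np.random.Generator:
    """Independent generator for a named stage, reproducible from one seed."""
    return np.random.default_rng([seed & 0x7FFFFFFF, zlib.crc32(label.encode())])


def default_mutation_matrix(ti_tv: float = 2.0, at_bias: float = 1.5) -> np.ndarray:
    """Rate-form 4x4 matrix (rows sum to zero), transition bias ti_tv and
    GC->AT rows accelerated by at_bias (the usual AT-ward mutation pressure,
    which puts the mutational GC equilibrium below 0.5)."""
    ti = {(0, 2), (2, 0), (1, 3), (3, 1)}          # A<->G, C<->T
    Q = np.zeros((4, 4))
    for x in range(4):
        for y in range(4):
            if x == y:
                continue
            Q[x, y] = ti_tv if (x, y) in ti else 1.0
        if x in GC_CODES:
            Q[x] *= at_bias
    np.fill_diagonal(Q, 0.0)
    Q /= Q.sum(axis=1).mean()            # mean total rate ~ 1
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


@dataclass
class SimConfig:
    """Study conditions for one synthetic run."""

    tree: Phylogeny
    length: int = 200_000
    mutation_matrix: np.ndarray = None
    context_multipliers: np.ndarray = None   # (4,4): [left, focal] rate scale
    kappa: float = 0.0                       # selection intensity on gc20
    rho: float = 1.0                         # divergence multiplier in cores
    pop_size: float = 10.0                   # N of the fixation function
    sel_window: int = 20                     # local-GC window (bp)
    core_gc: float = 0.25
    flank_gc: float = 0.55
    background_gc: float = 0.40
    core_len: tuple = (20, 40)
    flank_halfwidth: int = 300
    flank_peak_offset: int = 30
    flank_decay: float = 80.0
    coverage_mean: float = 30.0
    rare_base: float = 0.30                  # rare-allele mass at s = 0
    rare_slope: float = 0.08                 # per unit 4Ns
    seed: int = 0

    def __post_init__(self):
        if self.mutation_matrix is None:
            self.mutation_matrix = default_mutation_matrix()
        Q = np.asarray(self.mutation_matrix, dtype=float)
        off = Q - np.diag(np.diag(Q))
        if (off < 0).any() or not np.allclose(Q.sum(axis=1), 0, atol=1e-9):
            raise ValueError("mutation_matrix must be rate-form (rows sum to 0)")
        self.mutation_matrix = Q
        if self.context_multipliers is None:
            self.context_multipliers = np.ones((4, 4))
        self.context_multipliers = np.asarray(self.context_multipliers, float)
        if not 0 < self.rho <= 1:
            raise ValueError("rho must be in (0, 1]")
        if self.kappa < 0:
            raise ValueError("kappa must be >= 0")

    def expected_transition(self, t: float, left: int) -> np.ndarray:
        """First-order truth for learned tables: expm of the branch-scaled
        rate matrix with rows boosted by the left-flank context multiplier.
        Neighbor drift during the branch makes this approximate at O(t^2)."""
        from scipy.linalg import expm
        Q = self.mutation_matrix.copy()
        for x in range(4):
            Q[x] *= self.context_multipliers[left, x]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        return expm(t * Q)


@dataclass
class GCLandscape:
    length: int
    target_gc: np.ndarray
    ce_truth: list                     # (start, end) planted cores
    flank_halfwidth: int
    core_gc: float
    flank_gc: float
    background_gc: float

    def core_mask(self) -> np.ndarray:
        m = np.zeros(self.length, dtype=bool)
        for s, e in self.ce_truth:
            m[s:e] = True
        return m


@dataclass
class SubstitutionLog:
    """Every accepted substitution, in fixation order per branch."""

    events: list = field(default_factory=list)   # (branch, pos, from, to)

    def by_branch(self, branch):
        return [(p, f, t) for b, p, f, t in self.events if b == branch]

    def replay(self, tree: Phylogeny, root_codes: np.ndarray) -> dict:
        """Re-apply events down the tree; returns node name -> codes."""
        seqs = {tree.names[tree.root]: root_codes.copy()}
        per_branch = {}
        for b, p, f, t in self.events:
            per_branch.setdefault(b, []).append((p, f, t))
        for node in tree.preorder():
            if node == tree.root:
                continue
            name = tree.names[node]
            parent = tree.names[tree.parent[node]]
            seq = seqs[parent].copy()
            for p, f, t in per_branch.get(name, []):
                if seq[p] != f:
                    raise ValueError(f"inconsistent event at {p} on {name}")
                seq[p] = t
            seqs[name] = seq
        return seqs


# ---------------------------------------------------------------------------
# Landscape


def make_landscape(cfg: SimConfig, n_ces: int, spacing: str = "jittered",
                   rng: np.random.Generator | None = None) -> GCLandscape:
    """Plant non-overlapping AT cores with GC-elevated flanks.

    The target-GC profile is continuous and piecewise: a core plateau at
    core_gc, a linear ramp up to flank_gc peaking flank_peak_offset bp
    from the core edge, then a (truncated) exponential decay reaching
    background_gc exactly at flank_halfwidth from the edge.  Cores are
    separated by at least 2*flank_halfwidth so their flanks never overlap.
    """
    rng = rng or substream(cfg.seed, "landscape")
    L = cfg.length
    target = np.full(L, cfg.background_gc)
    if n_ces == 0:
        return GCLandscape(L, target, [], cfg.flank_halfwidth,
                           cfg.core_gc, cfg.flank_gc, cfg.background_gc)
    lens = rng.integers(cfg.core_len[0], cfg.core_len[1] + 1, size=n_ces)
    min_gap = 2 * cfg.flank_halfwidth
    edge = cfg.flank_halfwidth
    needed = int(lens.sum()) + (n_ces - 1) * min_gap + 2 * edge
    if needed > L:
        raise ValueError(f"cannot pack {n_ces} cores into {L} bp "
                         f"(needs >= {needed})")
    slack = L - needed
    if spacing == "jittered":
        extra = rng.multinomial(slack, np.full(n_ces + 1, 1 / (n_ces + 1)))
    elif spacing == "even":
        extra = np.full(n_ces + 1, slack // (n_ces + 1))
    else:
        raise ValueError(f"unknown spacing {spacing!r}")
    cores = []
    pos = edge + int(extra[0])
    for i in range(n_ces):
        cores.append((pos, pos + int(lens[i])))
        pos += int(lens[i]) + min_gap + int(extra[i + 1])

    d0, tau, E = cfg.flank_peak_offset, cfg.flank_decay, cfg.flank_halfwidth
    d = np.arange(1, E + 1, dtype=float)
    ramp = d <= d0
    prof = np.empty(E)
    prof[ramp] = cfg.core_gc + (cfg.flank_gc - cfg.core_gc) * d[ramp] / d0
    decay = (np.exp(-(d[~ramp] - d0) / tau) - np.exp(-(E - d0) / tau)) \
        / (1.0 - np.exp(-(E - d0) / tau))
    prof[~ramp] = cfg.background_gc + (cfg.flank_gc - cfg.background_gc) * decay
    for s, e in cores:
        target[s:e] = cfg.core_gc
        nright = min(E, L - e)
        target[e:e + nright] = prof[:nright]
        nleft = min(E, s)
        target[s - nleft:s] = prof[:nleft][::-1]
    return GCLandscape(L, target, cores, cfg.flank_halfwidth,
                       cfg.core_gc, cfg.flank_gc, cfg.background_gc)


# ---------------------------------------------------------------------------
# Sequence evolution


@njit(cache=True)
def _fixation(s, two_N):
    if abs(s) < 1e-12:
        return 1.0 / two_N
    z = two_N * 2.0 * s
    if z < -700.0:
        return np.exp((two_N * 2.0 - 2.0) * s)
    return (1.0 - np.exp(-2.0 * s)) / (1.0 - np.exp(-z))


@njit(cache=True)
def _branch_kernel(seq, is_gc, target, pos, u1, u2, u3,
                   row_tot, cum_target, mult, r_env, kappa, two_N, A,
                   halfw, out_pos, out_from, out_to):
    n = 0
    L = seq.shape[0]
    for i in range(pos.shape[0]):
        l = pos[i]
        x = seq[l]
        m = mult[seq[l - 1], x] if l > 0 else 1.0
        if u1[i] >= row_tot[x] * m / r_env:
            continue
        u = u2[i]
        y = 0
        while y < 3 and u > cum_target[x, y]:
            y += 1
        gx = is_gc[l]
        gy = 1 if (y == 1 or y == 2) else 0
        s = 0.0
        if kappa != 0.0 and gx != gy:
            lo = l - halfw // 2
            if lo < 0:
                lo = 0
            hi = l + (halfw - halfw // 2)
            if hi > L:
                hi = L
            cnt = hi - lo
            gc = 0
            for j in range(lo, hi):
                gc += is_gc[j]
            t_ = target[l]
            g_now = gc / cnt
            g_new = (gc + (gy - gx)) / cnt
            s = kappa * (abs(g_now - t_) - abs(g_new - t_))
        pi = _fixation(s, two_N)
        if not np.isfinite(pi):
            return -1
        if u3[i] < two_N * pi / A:
            seq[l] = y
            is_gc[l] = gy
            out_pos[n] = l
            out_from[n] = x
            out_to[n] = y
            n += 1
    return n


def _envelope_boost(cfg: SimConfig) -> float:
    """Largest relative fixation factor 2N*pi(s) over attainable s."""
    s_max = cfg.kappa / (cfg.sel_window // 2)   # truncated edge windows
    two_N = 2.0 * cfg.pop_size
    if s_max <= 0:
        return 1.0
    pi = (1.0 - np.exp(-2.0 * s_max)) / (1.0 - np.exp(-2.0 * two_N * s_max))
    return max(1.0, two_N * pi)


def _evolve_branch(seq, landscape, cfg, t, rng, branch, log):
    Q = cfg.mutation_matrix
    off = Q - np.diag(np.diag(Q))
    row_tot = off.sum(axis=1)
    cum_target = np.cumsum(off / row_tot[:, None], axis=1)[:, :3].copy()
    mult = cfg.context_multipliers
    r_env = row_tot.max() * mult.max()
    A = _envelope_boost(cfg)
    two_N = 2.0 * cfg.pop_size
    rho_l = np.ones(landscape.length)
    rho_l[landscape.core_mask()] = cfg.rho
    w = np.cumsum(rho_l)
    total = t * r_env * A * w[-1]
    K = rng.poisson(total)
    pos = np.searchsorted(w, rng.random(K) * w[-1]).astype(np.int64)
    u1, u2, u3 = rng.random(K), rng.random(K), rng.random(K)
    out_pos = np.empty(K, dtype=np.int64)
    out_from = np.empty(K, dtype=np.uint8)
    out_to = np.empty(K, dtype=np.uint8)
    is_gc = np.isin(seq, GC_CODES).astype(np.int64)
    n = _branch_kernel(seq, is_gc, landscape.target_gc, pos, u1, u2, u3,
                       row_tot, cum_target, mult, r_env, cfg.kappa, two_N, A,
                       cfg.sel_window, out_pos, out_from, out_to)
    if n < 0:
        raise FloatingPointError("nonfinite fixation probability")
    for i in range(n):
        log.events.append((branch, int(out_pos[i]),
                           int(out_from[i]), int(out_to[i])))
    return seq


def make_smooth_landscape(cfg: SimConfig, periods=(4000, 120),
                          amps=(0.13, 0.12), center: float = 0.45,
                          rng: np.random.Generator | None = None) -> GCLandscape:
    """Smooth multi-scale target-GC profile without planted cores.

    Superimposed sinusoids (random phases) give GC heterogeneity at both a
    regional scale and a finer sub-regional scale, all varying slowly
    relative to the 20 bp selection window.  This is the study landscape
    for polymorphism analyses, where the signal of interest is how
    allele frequencies track local GC within and across regional strata;
    sharp core/flank boundaries would put window-vs-point target
    mismatches right where SNP density is highest.
    """
    rng = rng or substream(cfg.seed, "smooth_landscape")
    L = cfg.length
    l = np.arange(L)
    target = np.full(L, center)
    for p, a in zip(periods, amps):
        target = target + a * np.sin(2 * np.pi * l / p + rng.uniform(0, 2 * np.pi))
    target = np.clip(target, 0.15, 0.8)
    return GCLandscape(L, target, [], cfg.flank_halfwidth,
                       cfg.core_gc, cfg.flank_gc, center)


def mutation_equilibrium_gc(cfg: SimConfig) -> float:
    """GC fraction of the stationary composition of the mutation matrix."""
    Q = cfg.mutation_matrix
    vals, vecs = np.linalg.eig(Q.T)
    pi = np.real(vecs[:, np.argmin(np.abs(vals))])
    pi = np.abs(pi) / np.abs(pi).sum()
    return float(pi[1] + pi[2])


def balance_sequence(landscape: GCLandscape, cfg: SimConfig,
                     tracking: float = 0.6,
                     rng: np.random.Generator | None = None) -> np.ndarray:
    """Reference sequence at approximate mutation-selection balance.

    The standing local GC is displaced from the selective target toward
    the mutational equilibrium: g*(l) = gc_mut + tracking * (target(l) -
    gc_mut).  An error-diffusion draw keeps realized window GC tightly on
    g* (far below binomial variance), emulating a regime where selection
    maintains local composition closely, so that in GC-rich elements the
    sequence sits systematically *below* its target (AT mutation
    pressure) — which is what makes further GC loss deleterious there.
    Used for polymorphism studies; the evolutionary simulator instead
    samples its root directly from the target profile.
    """
    rng = rng or substream(cfg.seed, "balance_seq")
    gc_mut = mutation_equilibrium_gc(cfg)
    gstar = gc_mut + tracking * (landscape.target_gc - gc_mut)
    L = landscape.length
    is_gc = np.empty(L, dtype=np.int64)
    err = 0.0
    u = rng.random(L)
    pick = rng.random(L) < 0.5
    gamma = 1.0
    for l in range(L):
        p = min(1.0, max(0.0, gstar[l] + gamma * err))
        s = 1 if u[l] < p else 0
        is_gc[l] = s
        err += gstar[l] - s
    seq = np.where(is_gc == 1, np.where(pick, 1, 2), np.where(pick, 0, 3))
    return seq.astype(np.uint8)


def sample_root(landscape: GCLandscape, rng) -> np.ndarray:
    """Root bases drawn per position from target_gc (G/C and A/T equiprobable
    within their class)."""
    L = landscape.length
    is_s = rng.random(L) < landscape.target_gc
    pick = rng.random(L) < 0.5
    seq = np.where(is_s, np.where(pick, 1, 2), np.where(pick, 0, 3))
    return seq.astype(np.uint8)


def evolve_alignment(landscape: GCLandscape, cfg: SimConfig,
                     burn_in: float = 0.0):
    """Evolve every branch of cfg.tree over the landscape.

    Returns (MultiAlignment of all nodes incl. ancestors kept as species
    rows only for leaves, SubstitutionLog, root codes).  With burn_in > 0
    the root sequence is first equilibrated for that many expected
    substitutions per site under the same dynamics, so it starts at
    mutation-selection balance rather than exactly on target.
    """
    tree = cfg.tree
    rng = substream(cfg.seed, "evolve")
    root = sample_root(landscape, rng)
    if burn_in > 0:
        dummy = SubstitutionLog()
        root = _evolve_branch(root.copy(), landscape, cfg, burn_in, rng,
                              "_burnin", dummy)
    log = SubstitutionLog()
    seqs = {tree.names[tree.root]: root}
    for node in tree.preorder():
        if node == tree.root:
            continue
        name = tree.names[node]
        parent = seqs[tree.names[tree.parent[node]]]
        seqs[name] = _evolve_branch(parent.copy(), landscape, cfg,
                                    float(tree.lengths[node]), rng, name, log)
    leaf_names = tree.leaf_names()
    ref = leaf_names[0]
    codes = np.vstack([seqs[n] for n in leaf_names])
    aln = MultiAlignment(leaf_names, codes, ref)
    return aln, log, root


# ---------------------------------------------------------------------------
# Selection coefficient shared with the SNP simulator


def selection_coefficients(codes: np.ndarray, target: np.ndarray,
                           pos: np.ndarray, alt: np.ndarray,
                           kappa: float, window: int = 20) -> np.ndarray:
    """s = kappa * (|gc20 - target| - |gc20' - target|) for a mutation
    codes[pos] -> alt, focal base included, windows truncated at edges."""
    L = len(codes)
    is_gc = np.isin(codes, GC_CODES).astype(np.int64)
    cum = np.concatenate(([0], np.cumsum(is_gc)))
    lo = np.maximum(pos - window // 2, 0)
    hi = np.minimum(pos + (window - window // 2), L)
    cnt = hi - lo
    gc = cum[hi] - cum[lo]
    delta = np.isin(alt, GC_CODES).astype(np.int64) - is_gc[pos]
    g_now = gc / cnt
    g_new = (gc + delta) / cnt
    t = target[pos]
    return kappa * (np.abs(g_now - t) - np.abs(g_new - t))


def local_gc20(codes: np.ndarray, pos: np.ndarray, window: int = 20):
    L = len(codes)
    is_gc = np.isin(codes, GC_CODES).astype(np.int64)
    cum = np.concatenate(([0], np.cumsum(is_gc)))
    lo = np.maximum(pos - window // 2, 0)
    hi = np.minimum(pos + (window - window // 2), L)
    return (cum[hi] - cum[lo]) / (hi - lo)


# ---------------------------------------------------------------------------
# SNP panel


def simulate_snps(landscape: GCLandscape, refseq, n_snps: int, cfg: SimConfig,
                  exclude_core_margin: int = 0, coverage=None):
    """SNP panel whose rare-allele mass tracks the selection coefficient.

    Positions are uniform outside cores (plus margin); the minor allele is
    drawn from the mutation matrix row of the reference base; the
    minor-allele frequency comes from a two-component spectrum whose rare
    component (maf < 0.05) has weight expit(logit(rare_base) -
    rare_slope * 4N * s), so deleterious minor alleles (s < 0) are rarer.
    """
    rng = substream(cfg.seed, "snps")
    codes = refseq if isinstance(refseq, np.ndarray) else encode_seq(refseq)
    allowed = np.ones(landscape.length, dtype=bool)
    for s, e in landscape.ce_truth:
        allowed[max(0, s - exclude_core_margin):e + exclude_core_margin] = False
    allowed &= codes < 4
    idx = np.flatnonzero(allowed)
    if n_snps > len(idx):
        raise ValueError(f"{n_snps} SNPs requested, {len(idx)} positions available")
    pos = np.sort(rng.choice(idx, size=n_snps, replace=False))
    x = codes[pos].astype(np.int64)
    Q = cfg.mutation_matrix - np.diag(np.diag(cfg.mutation_matrix))
    probs = Q / Q.sum(axis=1, keepdims=True)
    u = rng.random(n_snps)
    cum = np.cumsum(probs, axis=1)
    alt = (u[:, None] > cum[x]).sum(axis=1).astype(np.int64)
    s = selection_coefficients(codes, landscape.target_gc, pos, alt,
                               cfg.kappa, cfg.sel_window)
    p_rare = expit(logit(cfg.rare_base) - cfg.rare_slope * 4 * cfg.pop_size * s)
    rare = rng.random(n_snps) < p_rare
    maf = np.where(rare, rng.uniform(0.012, 0.05, n_snps),
                   rng.uniform(0.05, 0.5, n_snps))
    if coverage is None:
        cov = rng.poisson(cfg.coverage_mean, n_snps)
    else:
        cov = np.full(n_snps, coverage)
    bases = np.array(list("ACGT"))
    df = pd.DataFrame({
        "chrom": "chrS", "pos": pos,
        "allele1": bases[x], "allele2": bases[alt],
        "freq1": 1.0 - maf, "coverage": cov,
    })
    return snp_table_from_alleles(df)


# ---------------------------------------------------------------------------
# Signal tracks


def simulate_tracks(landscape: GCLandscape, refseq, cfg: SimConfig,
                    n_marks: int = 9, n_subsets: int = 3,
                    nuc_slope: float = 10.0, nuc_noise: float = 0.5,
                    mark_amp: float = 4.0, mark_sigma: float = 75.0,
                    binsize: int = 20):
    """Nucleosome-like track (logistic in binned GC) plus mark tracks with
    Gaussian bumps over disjoint core subsets; truth memberships returned."""
    rng = substream(cfg.seed, "tracks")
    codes = refseq if isinstance(refseq, np.ndarray) else encode_seq(refseq)
    n_bins = landscape.length // binsize
    trimmed = codes[: n_bins * binsize].reshape(n_bins, binsize)
    gc_bin = np.isin(trimmed, GC_CODES).mean(axis=1)
    centers = np.arange(n_bins) * binsize + binsize / 2
    nuc = expit(nuc_slope * (gc_bin - 0.5) + rng.normal(0, nuc_noise, n_bins))
    tracks = {"nucleosome": SignalTrackRaw("chrS", binsize, nuc)}
    cores = landscape.ce_truth
    core_subsets = rng.integers(0, n_subsets, size=len(cores))
    mark_subsets = np.arange(n_marks) % n_subsets
    for m in range(n_marks):
        vals = rng.normal(0, 1, n_bins)
        for ci, (s, e) in enumerate(cores):
            if core_subsets[ci] != mark_subsets[m]:
                continue
            mid = (s + e) / 2
            lo = np.searchsorted(centers, mid - 4 * mark_sigma)
            hi = np.searchsorted(centers, mid + 4 * mark_sigma)
            vals[lo:hi] += mark_amp * np.exp(
                -0.5 * ((centers[lo:hi] - mid) / mark_sigma) ** 2)
        tracks[f"mark{m}"] = SignalTrackRaw("chrS", binsize, vals)
    truth = {"core_subsets": core_subsets.tolist(),
             "mark_subsets": mark_subsets.tolist()}
    return tracks, truth


# ---------------------------------------------------------------------------
# Persistence


def write_truth(path, landscape: GCLandscape, log: SubstitutionLog | None = None,
                extra: dict | None = None):
    obj = {
        "length": landscape.length,
        "ce_truth": [list(c) for c in landscape.ce_truth],
        "core_gc": landscape.core_gc,
        "flank_gc": landscape.flank_gc,
        "background_gc": landscape.background_gc,
    }
    if log is not None:
        obj["n_events"] = len(log.events)
    if extra:
        obj.update(extra)
    with open(path, "w") as fh:
        json.dump(obj, fh)
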