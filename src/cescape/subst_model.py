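"""Flank-conditioned, per-branch substitution model with ancestral posteriors.

The model stores, for every branch b (identified by its child node) and
every pair of parent flanking bases (l, r), a 4x4 conditional probability
table P[b][(l,r)][x][y] = P(child = y | parent = x, flanks = (l, r)).
Parameters are learned by EM: the E-step runs per-position sum-product
(Felsenstein pruning) over the tree with flanks held fixed — taken from
the reference sequence on the first iteration and from posterior-mode
ancestral sequences afterwards — and the M-step re-estimates each table
from expected parent-child counts plus a pseudocount.

Conditioning substitution probabilities on flanking nucleotides corrects
the expected divergence for context effects (e.g. hypermutable
dinucleotides), which is what makes the observed/expected ratio a usable
conservation statistic in regions of unusual base composition.

Contexts are the 16 ordered ACGT flank pairs, coded l*4+r, plus a pooled
context (code 16) for positions whose flank is undetermined (sequence
edge, N, or gap); the pooled row is trained on all events regardless of
flank, a uniform-context fallback.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import product

import numpy as np

from .genome_io import MultiAlignment
from .phylo import Phylogeny

N_CTX = 17          # 16 flank pairs + pooled fallback
POOLED_CTX = 16


def context_ids(codes: np.ndarray) -> np.ndarray:
    """Per-position flank context from a coded sequence (0..5 per base).

    Position l gets context code(l-1)*4 + code(l+1) when both flanks are
    plain bases, else the pooled code.
    """
    L = len(codes)
    ctx = np.full(L, POOLED_CTX, dtype=np.int64)
    if L < 3:
        return ctx
    left = codes[:-2].astype(np.int64)
    right = codes[2:].astype(np.int64)
    ok = (left < 4) & (right < 4)
    inner = np.where(ok, left * 4 + right, POOLED_CTX)
    ctx[1:-1] = inner
    return ctx


@dataclass
class SubstModel:
    """Per-branch, flank-conditioned substitution probability tables.

    The root prior is flank-conditioned as well ((N_CTX, 4)); anchoring it
    to the empirical contextual base composition (rather than learning it)
    breaks a flat likelihood ridge in which substitution direction on the
    two root-adjacent branches trades off against root composition at
    exactly the contexts where rates are unusual.
    """

    branches: list                    # child-node names, one per branch
    P: np.ndarray                     # (n_branches, N_CTX, 4, 4)
    root_prior: np.ndarray            # (N_CTX, 4)
    alpha: float = 0.5
    flagged: list = field(default_factory=list)   # (branch, ctx, x) identity rows
    loglik_trace: list = field(default_factory=list)

    def __post_init__(self):
        self.root_prior = np.asarray(self.root_prior, dtype=float)
        if self.root_prior.ndim == 1:                 # context-free prior
            self.root_prior = np.broadcast_to(
                self.root_prior, (N_CTX, 4)).copy()
        sums = self.P.sum(axis=3)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("substitution tables are not row-stochastic")

    @classmethod
    def uniform(cls, branches, eps=0.05, alpha=0.5):
        P = np.full((len(branches), N_CTX, 4, 4), eps / 3)
        idx = np.arange(4)
        P[:, :, idx, idx] = 1.0 - eps
        return cls(branches, P, np.full((N_CTX, 4), 0.25), alpha=alpha)

    def branch_index(self, name):
        return self.branches.index(name)

    def to_json(self, path):
        obj = {
            "alpha": self.alpha,
            "root_prior": self.root_prior.tolist(),
            "branches": {
                b: {f"{'ACGT'[k // 4]}{'ACGT'[k % 4]}" if k < 16 else "pooled":
                    self.P[i, k].tolist() for k in range(N_CTX)}
                for i, b in enumerate(self.branches)
            },
        }
        with open(path, "w") as fh:
            json.dump(obj, fh)

    @classmethod
    def from_json(cls, path):
        with open(path) as fh:
            obj = json.load(fh)
        branches = list(obj["branches"])
        P = np.empty((len(branches), N_CTX, 4, 4))
        for i, b in enumerate(branches):
            for key, table in obj["branches"][b].items():
                k = POOLED_CTX if key == "pooled" else (
                    "ACGT".index(key[0]) * 4 + "ACGT".index(key[1]))
                P[i, k] = np.asarray(table)
        return cls(branches, P, np.asarray(obj["root_prior"]),
                   alpha=obj["alpha"])


@dataclass
class PosteriorTrack:
    """Joint parent-child posteriors per branch and node marginals."""

    branches: list                   # branch child-node names
    J: np.ndarray                    # (n_branches, L, 4, 4)
    node_marginals: dict             # node name -> (L, 4)
    parent_of: dict                  # branch name -> parent node name
    ctx: np.ndarray                  # (n_branches, L) contexts used
    loglik: float = 0.0

    @property
    def length(self):
        return self.J.shape[1]

    def branch_index(self, name):
        return self.branches.index(name)


@dataclass
class DivergenceTrack:
    """Posterior-expected and model-expected substitutions per position."""

    obs: np.ndarray
    exp: np.ndarray
    valid: np.ndarray
    chrom: str = "chr"

    @property
    def length(self):
        return len(self.obs)


# ---------------------------------------------------------------------------
# Inference


def _leaf_partial(codes: np.ndarray) -> np.ndarray:
    """(L, 4) clamped likelihood; gap/N rows marginalized to all-ones."""
    L = len(codes)
    beta = np.zeros((L, 4))
    known = codes < 4
    beta[known, codes[known].astype(np.int64)] = 1.0
    beta[~known] = 1.0
    return beta


def _branch_contexts(aln, tree, source_codes=None, per_branch=None):
    nb = len(tree.branch_nodes())
    if per_branch is not None:
        return per_branch
    if source_codes is None:
        source_codes = aln.ref_row()
    ctx = context_ids(source_codes)
    return np.broadcast_to(ctx, (nb, len(ctx))).copy()


def infer_posteriors(aln: MultiAlignment, tree: Phylogeny, model: SubstModel,
                     ctx: np.ndarray | None = None,
                     root_ctx: np.ndarray | None = None) -> PosteriorTrack:
    """Sum-product over the tree, positions independent given fixed flanks.

    Any node (leaf or internal) whose name appears among the alignment
    species is clamped to its observed bases; gap/N symbols are
    marginalized.  Joint parent-child posteriors are produced for every
    branch via an upward/downward pass with per-position rescaling.
    """
    L = aln.length
    branch_nodes = tree.branch_nodes()
    branches = [tree.names[i] for i in branch_nodes]
    b_index = {node: k for k, node in enumerate(branch_nodes)}
    if ctx is None:
        ctx = _branch_contexts(aln, tree)
    if root_ctx is None:
        root_ctx = context_ids(aln.ref_row())
    pi = model.root_prior[root_ctx]                   # (L, 4)
    observed = {}
    for i in range(tree.n_nodes):
        name = tree.names[i]
        if name in aln.species:
            observed[i] = aln.row(name)
    for i in tree.leaves():
        if i not in observed:
            raise ValueError(f"leaf {tree.names[i]!r} missing from alignment")

    # upward pass
    beta = [None] * tree.n_nodes
    msg = [None] * tree.n_nodes           # message from node to its parent
    logscale = np.zeros(L)
    for v in tree.postorder():
        if v in observed:
            b = _leaf_partial(observed[v])
            if tree.children[v]:
                for c in tree.children[v]:
                    b = b * msg[c]
        else:
            b = np.ones((L, 4))
            for c in tree.children[v]:
                b = b * msg[c]
        scale = b.max(axis=1)
        bad = scale <= 0
        if bad.any():
            raise FloatingPointError(
                f"zero likelihood at positions {np.flatnonzero(bad)[:5]}")
        b = b / scale[:, None]
        logscale += np.log(scale)
        beta[v] = b
        if v != tree.root:
            T = model.P[b_index[v]][ctx[b_index[v]]]       # (L,4,4)
            msg[v] = np.einsum("lxy,ly->lx", T, b)

    root_like = pi * beta[tree.root]
    norm = root_like.sum(axis=1)
    loglik = float(np.log(norm).sum() + logscale.sum())

    # downward pass
    outside = [None] * tree.n_nodes
    outside[tree.root] = pi.copy()
    J = np.empty((len(branch_nodes), L, 4, 4))
    marginals = {}
    for p in tree.preorder():
        m = outside[p] * beta[p]
        marginals[tree.names[p]] = m / m.sum(axis=1, keepdims=True)
        kids = tree.children[p]
        for c in kids:
            a = outside[p].copy()
            if p in observed:
                a = a * _leaf_partial(observed[p])
            for c2 in kids:
                if c2 != c:
                    a = a * msg[c2]
            k = b_index[c]
            T = model.P[k][ctx[k]]
            Jc = a[:, :, None] * T * beta[c][:, None, :]
            tot = Jc.sum(axis=(1, 2), keepdims=True)
            if not np.isfinite(tot).all() or (tot <= 0).any():
                raise FloatingPointError("nonfinite branch posterior")
            J[k] = Jc / tot
            o = np.einsum("lx,lxy->ly", a, T)
            outside[c] = o / o.max(axis=1, keepdims=True)
    parent_of = {tree.names[i]: tree.names[tree.parent[i]]
                 for i in branch_nodes}
    return PosteriorTrack(branches, J, marginals, parent_of, ctx, loglik)


# ---------------------------------------------------------------------------
# Learning


def _expected_counts(post: PosteriorTrack):
    nb = len(post.branches)
    counts = np.zeros((nb, N_CTX, 4, 4))
    for b in range(nb):
        ctx = post.ctx[b]
        for x, y in product(range(4), range(4)):
            counts[b, :, x, y] = np.bincount(
                ctx, weights=post.J[b, :, x, y], minlength=N_CTX)
    return counts


def _m_step(counts, root_counts, branches, alpha, min_opportunity=1e-8):
    # pooled fallback context accumulates everything
    counts = counts.copy()
    counts[:, POOLED_CTX] = counts[:, :16].sum(axis=1) + counts[:, POOLED_CTX]
    P = counts + alpha
    P /= P.sum(axis=3, keepdims=True)
    flagged = []
    opp = counts.sum(axis=3)
    for b, k, x in zip(*np.nonzero(opp < min_opportunity)):
        P[b, k, x] = np.eye(4)[x]
        flagged.append((branches[b], int(k), int(x)))
    rc = root_counts + alpha
    rc[POOLED_CTX] = root_counts[:16].sum(axis=0) + root_counts[POOLED_CTX] + alpha
    root_prior = rc / rc.sum(axis=1, keepdims=True)
    return P, root_prior, flagged


def empirical_root_prior(aln: MultiAlignment, alpha: float = 0.5) -> np.ndarray:
    """Contextual base composition averaged over species rows — the anchor
    for the root prior under the near-stationarity assumption."""
    counts = np.zeros((N_CTX, 4))
    for sp in aln.species:
        codes = aln.row(sp)
        ctx = context_ids(codes)
        known = codes < 4
        np.add.at(counts, (ctx[known], codes[known].astype(np.int64)), 1.0)
    counts[POOLED_CTX] += counts[:16].sum(axis=0)
    counts += alpha
    return counts / counts.sum(axis=1, keepdims=True)


def _mode_codes(marginals: dict, name: str) -> np.ndarray:
    return np.argmax(marginals[name], axis=1).astype(np.uint8)


def learn_model(aln: MultiAlignment, tree: Phylogeny, n_iter: int = 2,
                alpha: float = 0.5, flank_strategy: str = "ancestral",
                root_prior: str = "empirical",
                init: SubstModel | None = None) -> SubstModel:
    """EM fit of the flank-conditioned model.

    flank_strategy "ancestral" uses the reference flanks on the first
    iteration and posterior-mode parent-node flanks afterwards;
    "reference" keeps reference flanks throughout (contexts then never
    change between iterations, so the data log-likelihood is
    non-decreasing across the whole run).

    root_prior "empirical" (default) pins the contextual root prior to the
    mean contextual composition of the aligned species and never updates
    it; "learn" re-estimates it each M-step (exposes the root-direction
    likelihood ridge and is only advisable with external constraints).
    """
    branch_nodes = tree.branch_nodes()
    branches = [tree.names[i] for i in branch_nodes]
    pinned = empirical_root_prior(aln, alpha) if root_prior == "empirical" \
        else None
    if init is not None:
        model = init
    else:
        model = SubstModel.uniform(branches, alpha=alpha)
        if pinned is not None:
            model.root_prior = pinned.copy()
    ctx = _branch_contexts(aln, tree)
    root_ctx = context_ids(aln.ref_row())
    trace = []
    rname = tree.names[tree.root]
    for it in range(n_iter):
        post = infer_posteriors(aln, tree, model, ctx, root_ctx)
        trace.append(post.loglik)
        counts = _expected_counts(post)
        root_counts = np.zeros((N_CTX, 4))
        marg = post.node_marginals[rname]
        for x in range(4):
            root_counts[:, x] = np.bincount(root_ctx, weights=marg[:, x],
                                            minlength=N_CTX)
        P, learned_prior, flagged = _m_step(counts, root_counts, branches, alpha)
        prior = pinned if pinned is not None else learned_prior
        model = SubstModel(branches, P, prior.copy(), alpha=alpha,
                           flagged=flagged)
        if flank_strategy == "ancestral":
            for k, node in enumerate(branch_nodes):
                pname = tree.names[tree.parent[node]]
                codes = (aln.row(pname) if pname in aln.species
                         else _mode_codes(post.node_marginals, pname))
                ctx[k] = context_ids(codes)
            root_codes = (aln.row(rname) if rname in aln.species
                          else _mode_codes(post.node_marginals, rname))
            root_ctx = context_ids(root_codes)
    model.loglik_trace = trace
    return model


# ---------------------------------------------------------------------------
# Divergence statistic


def divergence_track(post: PosteriorTrack, model: SubstModel,
                     mask_vector: np.ndarray | None = None,
                     chrom: str = "chr") -> DivergenceTrack:
    """Observed and model-expected substitution counts summed over branches.

    obs[l] sums, over branches, the posterior probability that parent and
    child differ; exp[l] sums the substitution probability expected under
    the model given the parent-node marginal and the flank context used
    during inference.
    """
    L = post.length
    obs = np.zeros(L)
    exp = np.zeros(L)
    idx = np.arange(4)
    for k, bname in enumerate(post.branches):
        obs += 1.0 - post.J[k][:, idx, idx].sum(axis=1)
        M = post.node_marginals[post.parent_of[bname]]
        bi = model.branch_index(bname)
        pdiag = model.P[bi][post.ctx[k]][:, idx, idx]       # (L,4)
        exp += (M * (1.0 - pdiag)).sum(axis=1)
    valid = np.ones(L, dtype=bool) if mask_vector is None else ~mask_vector
    return DivergenceTrack(obs, exp, valid, chrom=chrom)
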