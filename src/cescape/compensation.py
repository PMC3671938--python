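"""GC gain/loss balance and tests for compensatory spatial coupling.

Two complementary tests for compensation between opposing substitutions:

* a non-parametric pairwise-alignment test — among pairs of diverged loci
  a fixed distance apart, the fraction where one locus has excess GC in
  species 1 and the other excess GC in species 2 (elevated at short
  distances under compensatory selection);
* a parametric single-lineage test — GC gain and loss events called from
  branch posteriors, then the rate of each event type conditioned on the
  presence of the same or the opposite type within a one-sided distance.

Plus the spatial gain/loss rate balance around conserved elements that
reproduces the AT-ward core / GC-ward flank signature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .profiles import nearest_signed_distance
from .subst_model import PosteriorTrack, SubstModel

GC = (1, 2)
AT = (0, 3)


@dataclass
class GCDeltaTrack:
    """Per-position GC difference between two aligned species.

    delta = [sp1 base is G/C] - [sp2 base is G/C] where both are aligned
    plain bases; NA (recorded in defined=False) at gaps and Ns.
    """

    delta: np.ndarray          # int8, meaningful only where defined
    diverged: np.ndarray       # bool
    defined: np.ndarray        # bool, False at gap/N

    @property
    def length(self):
        return len(self.delta)


def gc_delta(aln, sp1: str, sp2: str) -> GCDeltaTrack:
    a = aln.row(sp1)
    b = aln.row(sp2)
    defined = (a < 4) & (b < 4)
    ga = np.isin(a, GC).astype(np.int8)
    gb = np.isin(b, GC).astype(np.int8)
    delta = np.where(defined, ga - gb, 0).astype(np.int8)
    diverged = defined & (a != b)
    return GCDeltaTrack(delta, diverged, defined)


@dataclass
class CouplingCurve:
    distances: np.ndarray
    score: np.ndarray          # C(d), fraction of opposite-sign pairs
    n_pairs: np.ndarray
    ci_lo: np.ndarray
    ci_hi: np.ndarray

    def to_frame(self):
        return pd.DataFrame({"d": self.distances, "score": self.score,
                             "n": self.n_pairs, "ci_lo": self.ci_lo,
                             "ci_hi": self.ci_hi})


def coupling_curve(track: GCDeltaTrack, distances, maxgap: int = 4,
                   region: np.ndarray | None = None) -> CouplingCurve:
    """C(d) over pairs (l, l+d) with both loci diverged and delta-defined,
    at most maxgap undefined positions inside [l, l+d], optionally with l
    restricted to a boolean region mask.  95% CI is a normal-approx
    binomial with continuity correction."""
    gapcum = np.concatenate(([0], np.cumsum(~track.defined)))
    usable = track.diverged & track.defined & (track.delta != 0)
    distances = np.asarray(distances, dtype=np.int64)
    score = np.full(len(distances), np.nan)
    n_pairs = np.zeros(len(distances), dtype=np.int64)
    lo = np.full(len(distances), np.nan)
    hi = np.full(len(distances), np.nan)
    L = track.length
    for i, d in enumerate(distances):
        if d < 1 or d >= L:
            continue
        l = np.flatnonzero(usable[:-d] & usable[d:])
        if region is not None:
            l = l[region[l]]
        gaps = gapcum[l + d + 1] - gapcum[l]
        l = l[gaps <= maxgap]
        if len(l) == 0:
            continue
        prod = track.delta[l].astype(np.int64) * track.delta[l + d]
        k = int((prod == -1).sum())
        n = len(l)
        p = k / n
        half = (1.959964 * np.sqrt(p * (1 - p) / n) + 0.5 / n)
        score[i], n_pairs[i], lo[i], hi[i] = p, n, p - half, p + half
    return CouplingCurve(distances, score, n_pairs, lo, hi)


# ---------------------------------------------------------------------------
# Parametric (posterior-based) machinery


def lineage_events(post: PosteriorTrack, branch: str, tau: float = 0.9):
    """Positions whose posterior mass of GC-gaining (AT parent, GC child)
    resp. GC-losing substitution on the branch exceeds tau."""
    if not 0.5 < tau < 1:
        raise ValueError("tau must be in (0.5, 1)")
    J = post.J[post.branch_index(branch)]
    gain = J[:, AT][:, :, GC].sum(axis=(1, 2))
    loss = J[:, GC][:, :, AT].sum(axis=(1, 2))
    return np.flatnonzero(gain > tau), np.flatnonzero(loss > tau)


def conditional_rate_test(gain: np.ndarray, loss: np.ndarray,
                          d_grid, n_positions: int,
                          scored: np.ndarray | None = None) -> pd.DataFrame:
    """Event rates conditioned on a same/opposite-type event within (0, d]
    one-sided (rightward).

    For each d and each (event type A, conditioning type B): the fraction
    of scored positions carrying an A event among positions that have a B
    event within (pos, pos+d].  Reports the opposite/same rate ratios for
    both types.
    """
    if len(gain) == 0 or len(loss) == 0:
        raise ValueError("both event sets must be non-empty")
    pos = np.arange(n_positions) if scored is None else np.flatnonzero(scored)
    is_gain = np.zeros(n_positions, dtype=bool)
    is_gain[gain] = True
    is_loss = np.zeros(n_positions, dtype=bool)
    is_loss[loss] = True
    gain_s, loss_s = np.sort(gain), np.sort(loss)
    rows = []
    for d in np.asarray(d_grid, dtype=np.int64):
        cond = {}
        for bname, barr in (("gain", gain_s), ("loss", loss_s)):
            nxt = np.searchsorted(barr, pos, side="right")
            has = (nxt < len(barr)) & (barr[np.minimum(nxt, len(barr) - 1)]
                                       <= pos + d)
            cond[bname] = has
        row = {"d": int(d)}
        for a, aflag in (("gain", is_gain), ("loss", is_loss)):
            for b in ("gain", "loss"):
                sel = cond[b]
                n = int(sel.sum())
                row[f"{a}|{b}"] = aflag[pos][sel].mean() if n else np.nan
                row[f"n|{b}"] = n
        row["gain_ratio"] = row["gain|loss"] / row["gain|gain"] \
            if row.get("gain|gain") else np.nan
        row["loss_ratio"] = row["loss|gain"] / row["loss|loss"] \
            if row.get("loss|loss") else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Spatial gain/loss balance


SUBST_TYPES = [(x, y) for x in range(4) for y in range(4) if x != y]


def rate_balance_profile(post: PosteriorTrack, model: SubstModel, ces,
                         halfwidth: int = 1000, binwidth: int = 20,
                         valid: np.ndarray | None = None) -> pd.DataFrame:
    """GC gain and loss rates (events per opportunity) by distance from the
    nearest CE center, plus all 12 directed substitution-type rates.

    gain_rate = posterior mass of AT->GC transitions / parent AT mass,
    summed over branches and positions in the bin; loss symmetric;
    balance = gain / (gain + loss).
    """
    centers = np.array([c.center if hasattr(c, "center") else int(c)
                        for c in ces], dtype=np.int64)
    L = post.length
    pos = np.arange(L, dtype=np.int64)
    d = nearest_signed_distance(pos, centers)
    keep = np.abs(d) <= halfwidth
    if valid is not None:
        keep &= valid
    pos, d = pos[keep], d[keep]
    nb = (2 * halfwidth) // binwidth + 1
    bins = (d + halfwidth) // binwidth
    gain_ev = np.zeros(L)
    loss_ev = np.zeros(L)
    at_opp = np.zeros(L)
    gc_opp = np.zeros(L)
    directed = np.zeros((12, L))
    opp = np.zeros((4, L))
    for k, bname in enumerate(post.branches):
        J = post.J[k]
        gain_ev += J[:, AT][:, :, GC].sum(axis=(1, 2))
        loss_ev += J[:, GC][:, :, AT].sum(axis=(1, 2))
        M = post.node_marginals[post.parent_of[bname]]
        at_opp += M[:, AT].sum(axis=1)
        gc_opp += M[:, GC].sum(axis=1)
        for t, (x, y) in enumerate(SUBST_TYPES):
            directed[t] += J[:, x, y]
        opp += M.T
    rows = []
    bases = "ACGT"
    for b in range(nb):
        sel = bins == b
        p = pos[sel]
        if len(p) == 0:
            continue
        at_o, gc_o = at_opp[p].sum(), gc_opp[p].sum()
        g = gain_ev[p].sum() / at_o if at_o > 0 else np.nan
        lo = loss_ev[p].sum() / gc_o if gc_o > 0 else np.nan
        row = {"offset": b * binwidth - halfwidth, "n": len(p),
               "gain_rate": g, "loss_rate": lo}
        tot = (g if np.isfinite(g) else 0) + (lo if np.isfinite(lo) else 0)
        row["balance"] = g / tot if np.isfinite(g) and np.isfinite(lo) \
            and tot > 0 else np.nan
        for t, (x, y) in enumerate(SUBST_TYPES):
            o = opp[x][p].sum()
            row[f"{bases[x]}>{bases[y]}"] = directed[t][p].sum() / o \
                if o > 0 else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def permutation_flatness(track: GCDeltaTrack, distances, maxgap: int = 4,
                         n_perm: int = 50, seed: int = 0) -> float:
    """Fraction of d-points whose permutation-null C(d) CI excludes the
    global mean, averaged over label-shuffled delta tracks."""
    rng = np.random.default_rng(seed)
    usable = np.flatnonzero(track.diverged & track.defined & (track.delta != 0))
    outside = 0
    total = 0
    for _ in range(n_perm):
        shuffled = track.delta.copy()
        shuffled[usable] = rng.permutation(track.delta[usable])
        perm = GCDeltaTrack(shuffled, track.diverged, track.defined)
        curve = coupling_curve(perm, distances, maxgap)
        ok = np.isfinite(curve.score)
        if not ok.any():
            continue
        mean = np.average(curve.score[ok], weights=curve.n_pairs[ok])
        outside += int(((curve.ci_lo[ok] > mean) | (curve.ci_hi[ok] < mean)).sum())
        total += int(ok.sum())
    return outside / total if total else np.nan
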