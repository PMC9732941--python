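"""Independent brute-force oracles used only by the tests.

Each oracle recomputes a quantity by enumeration or direct summation,
deliberately avoiding the code paths (and library calls) it checks.
"""

from __future__ import annotations

import itertools
from fractions import Fraction
from math import comb

import numpy as np


# --------------------------------------------------------------------------
# intervals


def brute_overlap_pairs(peaks, tes):
    """All (peak_index, te_row_index, overlap_bp) by O(n*m) scan."""
    out = []
    for pi, p in peaks.reset_index(drop=True).iterrows():
        for ti, t in tes.reset_index(drop=True).iterrows():
            if p["chrom"] != t["chrom"]:
                continue
            ov = min(p["end"], t["end"]) - max(p["start"], t["start"])
            if ov >= 1:
                out.append((pi, ti, ov))
    return sorted(out)


def brute_merge(tes, max_gap):
    """Transitive-closure merge of same-copy fragments, all-pairs."""
    rows = []
    for (chrom, fam, cid), sub in tes.groupby(["chrom", "family", "copy_id"]):
        iv = [[s, e] for s, e in zip(sub["start"], sub["end"])]
        merged = True
        while merged:
            merged = False
            for a, b in itertools.combinations(range(len(iv)), 2):
                if iv[a] is None or iv[b] is None:
                    continue
                (s1, e1), (s2, e2) = iv[a], iv[b]
                gap = max(s1, s2) - min(e1, e2)
                if gap <= max_gap:  # overlap counts as gap <= 0
                    iv[a] = [min(s1, s2), max(e1, e2)]
                    iv[b] = None
                    merged = True
            iv = [x for x in iv if x is not None]
        for s, e in iv:
            rows.append((chrom, fam, cid, s, e))
    return sorted(rows)


# --------------------------------------------------------------------------
# parsimony


def enumerate_mpr(tree, tipstates):
    """MPR state sets and parsimony length by exhaustive enumeration.

    Considers every assignment of {0,1} to internal nodes (and to tips
    with missing state -1); counts state changes over all branches.
    Returns (node label -> frozenset of optimal states, min length).
    """
    fixed = {}
    free = []
    for v in range(tree.n_nodes):
        if tree.children[v]:
            free.append(v)
        else:
            s = tipstates[tree.labels[v]]
            if s == -1:
                free.append(v)
            else:
                fixed[v] = int(s)
    best = None
    optimal = []
    for combo in itertools.product((0, 1), repeat=len(free)):
        state = dict(fixed)
        state.update(zip(free, combo))
        changes = sum(
            state[v] != state[tree.parent[v]]
            for v in range(tree.n_nodes)
            if tree.parent[v] != -1
        )
        if best is None or changes < best:
            best = changes
            optimal = [state]
        elif changes == best:
            optimal.append(state)
    sets = {
        tree.labels[v]: frozenset(st[v] for st in optimal)
        for v in range(tree.n_nodes)
    }
    return sets, best


# --------------------------------------------------------------------------
# exact tests


def binom_pvalue_minlike(k, n, p, gamma=1e-7):
    """Two-sided binomial p by direct pmf summation (minimum-likelihood rule).

    Includes every outcome whose pmf is <= pmf(k) within relative slack
    ``gamma`` (the standard tie tolerance of the minlike convention).
    """
    def pmf(i):
        return comb(n, i) * (p**i) * ((1 - p) ** (n - i))

    d = pmf(k)
    return min(1.0, sum(pmf(i) for i in range(n + 1) if pmf(i) <= d * (1 + gamma)))


def hypergeom_sf_exact(k, N, m, n):
    """P(X >= k), X ~ Hypergeom(N, m, n), by exact rational summation."""
    total = Fraction(0)
    denom = comb(N, n)
    for i in range(k, min(m, n) + 1):
        total += Fraction(comb(m, i) * comb(N - m, n - i), denom)
    return float(total)


def wilcoxon_exact_p(x, y):
    """Exact two-sided rank-sum p by full enumeration of group assignments.

    Assumes no ties. p = min(1, 2*min(P(W <= w), P(W >= w))) where W is the
    rank sum of the first group over all equally likely assignments.
    """
    x, y = list(x), list(y)
    pooled = sorted(x + y)
    assert len(set(pooled)) == len(pooled), "oracle assumes no ties"
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    w_obs = sum(ranks[v] for v in x)
    n = len(x)
    ws = np.array(
        [
            sum(i + 1 for i in combo)
            for combo in itertools.combinations(range(len(pooled)), n)
        ]
    )
    p_le = np.mean(ws <= w_obs)
    p_ge = np.mean(ws >= w_obs)
    return min(1.0, 2 * min(p_le, p_ge))


def bh_stepup(pvals):
    """Hand-rolled Benjamini-Hochberg step-up q-values."""
    p = np.asarray(pvals, float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    prev = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        rank = m - rank_from_top
        prev = min(prev, p[idx] * m / rank)
        q[idx] = prev
    return q


def f_sf_numeric(F, d1, d2):
    """P(F_{d1,d2} >= F) by numerical integration of the density."""
    from scipy.integrate import quad
    from scipy.special import betaln

    def dens(x):
        logc = 0.5 * (d1 * np.log(d1) + d2 * np.log(d2)) - betaln(d1 / 2, d2 / 2)
        return np.exp(
            logc + (d1 / 2 - 1) * np.log(x) - ((d1 + d2) / 2) * np.log(d2 + d1 * x)
        )

    val, _ = quad(dens, F, np.inf, limit=400)
    return val


def enumerate_mpr_matrix(tree, states):
    """Vectorized exhaustive-enumeration MPR sets for many binary characters.

    ``states``: (n_chars, n_tips) array of 0/1 tip states in the order of
    ``tree.tip_indices``. Enumerates every assignment of {0,1} to internal
    nodes and returns (state_sets (n_chars, n_nodes, 2) bool, lengths).
    """
    import itertools as _it

    tips = list(tree.tip_indices)
    tip_pos = {v: j for j, v in enumerate(tips)}
    internal = [v for v in range(tree.n_nodes) if tree.children[v]]
    int_pos = {v: j for j, v in enumerate(internal)}
    A = np.array(list(_it.product((0, 1), repeat=len(internal))), dtype=np.int8)
    n_a, G = len(A), states.shape[0]

    cost = np.zeros((n_a, G), dtype=np.int32)
    for v in range(tree.n_nodes):
        u = tree.parent[v]
        if u == -1:
            continue
        pu = A[:, int_pos[u]]
        if v in int_pos:
            cost += (A[:, int_pos[v]] != pu)[:, None]
        else:
            cost += pu[:, None] != states[:, tip_pos[v]][None, :]

    lengths = cost.min(axis=0)
    optimal = cost == lengths[None, :]
    sets = np.zeros((G, tree.n_nodes, 2), dtype=bool)
    for v in range(tree.n_nodes):
        if v in int_pos:
            col = A[:, int_pos[v]]
            for s in (0, 1):
                sets[:, v, s] = (optimal & (col == s)[:, None]).any(axis=0)
        else:
            s = states[:, tip_pos[v]]
            sets[np.arange(G), v, s] = True
    return sets, lengths


def brute_overlap_pairs_np(peaks, tes):
    """Quadratic all-pairs overlap by broadcasting (single chromosome)."""
    ps, pe = peaks["start"].to_numpy(), peaks["end"].to_numpy()
    ts, te = tes["start"].to_numpy(), tes["end"].to_numpy()
    ov = np.minimum(pe[:, None], te[None, :]) - np.maximum(ps[:, None], ts[None, :])
    ii, jj = np.nonzero(ov >= 1)
    return sorted(zip(ii.tolist(), jj.tolist(), ov[ii, jj].tolist()))
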