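"""Parsimony reconstruction of gene-expression gains and losses.

Genes are scored expressed (TPM >= 2) or not expressed per taxon, and the
resulting binary characters are optimized on a rooted species tree by
unweighted (Fitch) parsimony. For every node we report the *MPR state
set* — the states the node takes in at least one most-parsimonious
reconstruction — computed exactly by a unit-cost dynamic program:

* down-pass: ``down[v][s]`` = minimum changes in the subtree of ``v``
  given ``v`` has state ``s`` (Sankoff recursion, valid for
  multifurcations);
* up-pass: ``up[v][s]`` = minimum changes in the rest of the tree given
  ``v`` has state ``s``;
* MPR set of ``v`` = argmin over ``s`` of ``down+up``; the parsimony
  length is the shared minimum.

A branch (u -> v) carries an *unambiguous gain* when the MPR set of u is
exactly {0} and that of v exactly {1} (loss: the reverse). Branches
touching an ambiguous node contribute no event; missing tips (``?``)
contribute both states and never create events. The recruitment age of a
gene for a focal taxon is the most tipward unambiguous gain on the
root-to-tip path, or "ancestral" when the root is unambiguously
expressed.

The two branches incident to the root deserve a caveat: a single change
there always leaves the root MPR set ambiguous, so such events are
invisible by design — parsimony cannot polarize them without an
additional outgroup.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

_BIG = 10**6  # effectively +inf for unit-cost DP on <=1e5 branches
MISSING = -1


@dataclass
class PhyloTree:
    """Array view of a rooted tree (root = basal node of the Newick string).

    Internal nodes without labels get deterministic preorder names
    ``N1, N2, ...`` so branches can be keyed by their child node.
    """

    labels: list            # per node
    parent: np.ndarray      # parent index, -1 for root
    children: list          # list of child-index lists
    postorder: np.ndarray   # node indices, children before parents
    edge_lengths: np.ndarray  # branch length above each node (0 for root)
    newick: str

    @property
    def root(self) -> int:
        return int(self.postorder[-1])

    @property
    def n_nodes(self) -> int:
        return len(self.labels)

    @property
    def tip_indices(self) -> np.ndarray:
        return np.array([i for i, ch in enumerate(self.children) if not ch])

    @property
    def tip_labels(self) -> list:
        return [self.labels[i] for i in self.tip_indices]

    def label_index(self) -> dict:
        return {lab: i for i, lab in enumerate(self.labels)}

    def path_to_tip(self, tip_label: str) -> list:
        """Node indices from root to the tip, inclusive."""
        idx = self.label_index()
        if tip_label not in idx:
            raise ValueError(f"focal tip {tip_label!r} not in tree")
        node = idx[tip_label]
        path = [node]
        while self.parent[node] != -1:
            node = int(self.parent[node])
            path.append(node)
        return path[::-1]

    def clade_tips(self, node: int) -> frozenset:
        out = []
        stack = [node]
        while stack:
            n = stack.pop()
            if not self.children[n]:
                out.append(self.labels[n])
            stack.extend(self.children[n])
        return frozenset(out)


def parse_tree(newick: str, min_tips: int = 2) -> PhyloTree:
    """Parse a Newick string into a :class:`PhyloTree`.

    The tree is taken as rooted at the basal node as written. Trees with
    fewer than ``min_tips`` leaves are rejected.
    """
    try:
        dt = dendropy.Tree.get(data=newick, schema="newick",
                               suppress_internal_node_taxa=True,
                               preserve_underscores=True)
    except Exception as exc:  # dendropy's parse errors are not ValueErrors
        raise ValueError(f"could not parse Newick tree: {exc}") from exc
    nodes = list(dt.preorder_node_iter())
    n_unnamed = 0
    labels, parent, children, elens = [], [], [], []
    index = {}
    for i, nd in enumerate(nodes):
        index[id(nd)] = i
        if nd.taxon is not None:
            labels.append(nd.taxon.label)
        elif nd.label:
            labels.append(nd.label)
        else:
            n_unnamed += 1
            labels.append(f"N{n_unnamed}")
        parent.append(index[id(nd.parent_node)] if nd.parent_node else -1)
        children.append([])
        elens.append(nd.edge.length if nd.edge.length is not None else 0.0)
    for i, p in enumerate(parent):
        if p >= 0:
            children[p].append(i)
    post = [index[id(nd)] for nd in dt.postorder_node_iter()]
    tree = PhyloTree(
        labels=labels,
        parent=np.asarray(parent),
        children=children,
        postorder=np.asarray(post),
        edge_lengths=np.asarray(elens, dtype=float),
        newick=newick,
    )
    n_tips = len(tree.tip_indices)
    if n_tips < min_tips:
        raise ValueError(f"tree has {n_tips} tip(s); need >= {min_tips}")
    if len(set(tree.tip_labels)) != n_tips:
        raise ValueError("duplicate tip labels")
    return tree


def binarize_expression(tpm: pd.DataFrame, threshold: float = 2.0) -> pd.DataFrame:
    """Binarize a gene x taxon TPM matrix: 1 iff TPM >= threshold.

    Missing TPM (NaN) becomes ``-1`` (unknown state). Negative TPM raises.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    vals = tpm.to_numpy(dtype=float)
    if (vals < 0).any():
        raise ValueError("negative TPM values")
    out = np.where(np.isnan(vals), MISSING, (vals >= threshold).astype(int))
    return pd.DataFrame(out.astype(np.int8), index=tpm.index, columns=tpm.columns)


@dataclass
class Reconstruction:
    """MPR state sets and parsimony lengths for a character matrix.

    ``state_sets[g, v, s]`` is True when state ``s`` at node ``v`` occurs
    in a most-parsimonious reconstruction of gene ``g``.
    """

    tree: PhyloTree
    genes: list
    state_sets: np.ndarray   # (n_genes, n_nodes, 2) bool
    lengths: np.ndarray      # (n_genes,) int

    def node_set(self, gene, node_label) -> frozenset:
        g = self.genes.index(gene)
        v = self.tree.label_index()[node_label]
        return frozenset(s for s in (0, 1) if self.state_sets[g, v, s])


def reconstruct_matrix(tree: PhyloTree, binmat: pd.DataFrame) -> Reconstruction:
    """Exact MPR state sets for every gene (row) of a binary matrix.

    Columns must exactly cover the tree's tip labels; values are 0, 1, or
    ``-1`` for missing. Vectorized across genes.
    """
    tips = tree.tip_labels
    if set(binmat.columns) != set(tips):
        raise ValueError("matrix taxa do not match tree tip labels")
    states = binmat[tips].to_numpy()
    if not np.isin(states, (0, 1, MISSING)).all():
        raise ValueError("binary matrix may contain only 0, 1, -1")
    G, n = len(binmat), tree.n_nodes

    down = np.zeros((n, G, 2), dtype=np.int32)
    tip_pos = {v: j for j, v in enumerate(tree.tip_indices)}
    for v in tree.postorder:
        ch = tree.children[v]
        if not ch:
            s = states[:, tip_pos[v]]
            down[v, s == 0, 1] = _BIG
            down[v, s == 1, 0] = _BIG
            continue
        for s in (0, 1):
            acc = np.zeros(G, dtype=np.int32)
            for c in ch:
                acc += np.minimum(down[c, :, s], down[c, :, 1 - s] + 1)
            down[v, :, s] = acc

    up = np.zeros((n, G, 2), dtype=np.int32)
    for v in tree.postorder[::-1]:
        for c in tree.children[v]:
            # cost of the rest of the tree for child c having state s:
            # min over parent state su of up[v][su] + (down[v][su] minus
            # c's own contribution) + change indicator
            best = np.full((G, 2), _BIG, dtype=np.int32)
            for su in (0, 1):
                m_c = np.minimum(down[c, :, su], down[c, :, 1 - su] + 1)
                base = up[v, :, su] + down[v, :, su] - m_c
                for s in (0, 1):
                    best[:, s] = np.minimum(best[:, s], base + (1 if s != su else 0))
            up[c] = best

    total = down + up
    lengths = total[tree.root].min(axis=1)
    state_sets = np.transpose(total, (1, 0, 2)) <= lengths[:, None, None]
    return Reconstruction(
        tree=tree, genes=list(binmat.index),
        state_sets=state_sets, lengths=lengths.astype(int),
    )


def fitch_ancestral(tree: PhyloTree, tipstates: dict | pd.Series) -> tuple[dict, int]:
    """MPR state sets for a single character.

    ``tipstates`` maps tip label -> 0/1/-1. Returns
    ``(node label -> frozenset of states, parsimony length)``. Every tip of
    the tree must appear in ``tipstates``.
    """
    tipstates = dict(tipstates)
    missing_tips = set(tree.tip_labels) - set(tipstates)
    if missing_tips:
        raise ValueError(f"tips without a state: {sorted(missing_tips)}")
    mat = pd.DataFrame([tipstates], index=["char"])
    recon = reconstruct_matrix(tree, mat)
    sets = {
        tree.labels[v]: frozenset(s for s in (0, 1) if recon.state_sets[0, v, s])
        for v in range(tree.n_nodes)
    }
    return sets, int(recon.lengths[0])


@dataclass
class GainLossResult:
    """Unambiguous gains/losses per branch, with per-gene event rows."""

    branch_counts: pd.DataFrame  # child_label, n_gains, n_losses
    events: pd.DataFrame         # gene, branch (child label), direction
    recruitment: pd.Series | None  # gene -> clade label / "ancestral" / None


def call_gain_loss(
    recon: Reconstruction, focal_tip: str | None = None
) -> GainLossResult:
    """Call unambiguous per-branch expression gains and losses.

    A branch (parent u -> child v) carries a gain for a gene iff the MPR
    set of u is {0} and of v is {1}; a loss is the reverse. With a
    ``focal_tip``, each gene's recruitment label is the child-node label
    of the most tipward unambiguous gain on the root-to-tip path;
    "ancestral" when the root set is {1}; ``None`` otherwise.
    """
    tree = recon.tree
    ss = recon.state_sets  # (G, n, 2)
    only0 = ss[:, :, 0] & ~ss[:, :, 1]
    only1 = ss[:, :, 1] & ~ss[:, :, 0]

    rows = []
    counts = []
    for v in range(tree.n_nodes):
        u = tree.parent[v]
        if u == -1:
            continue
        gains = only0[:, u] & only1[:, v]
        losses = only1[:, u] & only0[:, v]
        counts.append((tree.labels[v], int(gains.sum()), int(losses.sum())))
        for g in np.nonzero(gains)[0]:
            rows.append((recon.genes[g], tree.labels[v], "gain"))
        for g in np.nonzero(losses)[0]:
            rows.append((recon.genes[g], tree.labels[v], "loss"))
    branch_counts = pd.DataFrame(counts, columns=["child_label", "n_gains", "n_losses"])
    events = pd.DataFrame(rows, columns=["gene", "branch", "direction"])

    recruitment = None
    if focal_tip is not None:
        path = tree.path_to_tip(focal_tip)
        root = tree.root
        labels = []
        for g in range(len(recon.genes)):
            label = None
            # walk tipward; remember the last unambiguous gain
            for u, v in zip(path[:-1], path[1:]):
                if only0[g, u] and only1[g, v]:
                    label = tree.labels[v]
            if label is None and only1[g, root]:
                label = "ancestral"
            labels.append(label)
        recruitment = pd.Series(labels, index=recon.genes, name="recruitment")
    return GainLossResult(branch_counts=branch_counts, events=events,
                          recruitment=recruitment)
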