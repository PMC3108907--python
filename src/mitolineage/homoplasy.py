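"""Distance-based genealogy surrogate and per-site homoplasy indices.

A neighbor-joining tree stands in for an externally estimated genealogy;
per segregating site the parsimony step count s on that tree is compared
with the minimum possible m (= number of observed states - 1) and the
star-tree maximum g (= number of genomes carrying a variant state, i.e.
total state count minus the largest state count), giving the classic
character-fit indices

    CI = m / s          consistency index
    HI = 1 - CI         homoplasy index
    RI = (g - s)/(g - m) retention index (:= 1 when g = m)
    RC = CI * RI        rescaled consistency index

CI < 1 diagnoses recurrent (homoplasious) mutation at the site, the
mechanism by which hypervariable D-loop positions erode genealogical
signal.  The indices are tree-conditional: any user-supplied newick can
replace the NJ surrogate.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

from .diversity import DistanceMatrix, SiteReport, segregating_sites
from .io import Alignment, PartitionMap

__all__ = ["SiteHomoplasy", "nj_tree", "fitch_steps", "site_indices"]

_STATE_BIT = {"A": 1, "C": 2, "G": 4, "T": 8, "N": 15, "-": 15}
_BASES = "ACGT"
_INF = 10**9


def nj_tree(dm: DistanceMatrix) -> dendropy.Tree:
    """Neighbor-joining tree from a symmetric distance matrix.

    Standard Q-criterion agglomeration.  Ties on Q are broken by the
    lowest (i, j) index pair in the current node ordering, so the result
    is deterministic.  Negative branch lengths are floored at zero with
    the deficit shifted onto the sibling branch (their sum is preserved).
    The final three nodes join at an unresolved (trifurcating) root, the
    usual unrooted representation.
    """
    n = dm.n
    if n < 3:
        raise ValueError("neighbor-joining needs >= 3 labels")
    taxa = dendropy.TaxonNamespace(dm.labels)
    nodes: list[dendropy.Node] = []
    for label in dm.labels:
        nd = dendropy.Node(taxon=taxa.get_taxon(label))
        nodes.append(nd)
    d = dm.d.astype(float).copy()
    active = list(range(n))

    def _join(i: int, j: int, li: float, lj: float) -> dendropy.Node:
        # floor negative branch lengths, moving the deficit to the sibling
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        parent = dendropy.Node()
        nodes[i].edge.length = max(li, 0.0)
        nodes[j].edge.length = max(lj, 0.0)
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        return parent

    while len(active) > 2:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # lowest-index tie-break: scan in row-major order
        best = np.unravel_index(np.argmin(q), q.shape)
        ii, jj = sorted(best)
        i, j = active[ii], active[jj]
        dij = d[i, j]
        li = 0.5 * dij + (r[ii] - r[jj]) / (2 * (m - 2))
        lj = dij - li
        parent = _join(i, j, li, lj)
        # distances from the new node
        new_row = 0.5 * (d[i, :] + d[j, :] - dij)
        d[i, :] = new_row
        d[:, i] = new_row
        d[i, i] = 0.0
        nodes[i] = parent
        active.remove(j)

    if len(active) == 2:
        i, j = active
        root = dendropy.Node()
        nodes[i].edge.length = max(d[i, j], 0.0)
        nodes[j].edge.length = 0.0
        root.add_child(nodes[i])
        root.add_child(nodes[j])
    else:
        root = nodes[active[0]]
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.seed_node = root
    tree.is_rooted = False
    return tree


def _tip_bits(tree: dendropy.Tree, states: dict[str, str]) -> None:
    for leaf in tree.leaf_node_iter():
        label = leaf.taxon.label
        if label not in states:
            raise ValueError(f"no state assigned to tip {label}")
        ch = states[label].upper()
        if ch not in _STATE_BIT:
            raise ValueError(f"invalid state {ch!r} at tip {label}")


def fitch_steps(tree: dendropy.Tree, states: dict[str, str]) -> int:
    """Minimum number of state changes for one site on the tree.

    Unit-cost Sankoff dynamic program over {A,C,G,T}; N and - at a tip
    allow any state for free.  Exact on multifurcating trees (an
    unrooted NJ tree carries a basal trifurcation) and invariant to the
    rooting chosen, unlike the two-pass set heuristic.
    """
    _tip_bits(tree, states)
    cost: dict[dendropy.Node, np.ndarray] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            bits = _STATE_BIT[states[node.taxon.label].upper()]
            c = np.array(
                [0 if bits & (1 << k) else _INF for k in range(4)], dtype=np.int64
            )
        else:
            c = np.zeros(4, dtype=np.int64)
            for child in node.child_nodes():
                cc = cost[child]
                best = cc.min()
                # min over child states of cost + [state change]
                c += np.minimum(cc, best + 1)
        cost[node] = c
    return int(cost[tree.seed_node].min())


def sankoff_assign(tree: dendropy.Tree, states: dict[str, str]) -> tuple[dict, bool]:
    """Deterministic minimum-change ancestral states for one site.

    Backtracks the unit-cost DP: the root takes the lexicographically
    first minimum-cost state; each child keeps its parent's state when
    that is optimal, otherwise takes the lexicographically first optimal
    state.  Returns (node -> state char, ambiguous) where ``ambiguous``
    records whether any choice had a tie beyond the fixed rule.
    """
    _tip_bits(tree, states)
    cost: dict[dendropy.Node, np.ndarray] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            bits = _STATE_BIT[states[node.taxon.label].upper()]
            c = np.array(
                [0 if bits & (1 << k) else _INF for k in range(4)], dtype=np.int64
            )
        else:
            c = np.zeros(4, dtype=np.int64)
            for child in node.child_nodes():
                cc = cost[child]
                c += np.minimum(cc, cc.min() + 1)
        cost[node] = c
    assignment: dict[dendropy.Node, str] = {}
    ambiguous = False
    root = tree.seed_node
    root_c = cost[root]
    mins = np.flatnonzero(root_c == root_c.min())
    if len(mins) > 1:
        ambiguous = True
    assignment[root] = _BASES[mins[0]]
    for node in tree.preorder_node_iter():
        if node is root:
            continue
        parent_state = assignment[node.parent_node]
        pk = _BASES.index(parent_state)
        c = cost[node]
        # optimal child states given the parent's state
        scores = np.array([c[k] + (0 if k == pk else 1) for k in range(4)])
        opt = np.flatnonzero(scores == scores.min())
        if len(opt) > 1:
            ambiguous = True
        if pk in opt:
            assignment[node] = parent_state
        else:
            assignment[node] = _BASES[opt[0]]
    return assignment, ambiguous


@dataclass
class SiteHomoplasy:
    position: int
    locus: str
    locus_position: int | None  # 1-based within locus; None outside partitions
    states: str
    steps: int  # s, observed on the tree
    min_steps: int  # m = #states - 1
    max_steps: int  # g, star-tree steps
    ci: float
    hi: float
    ri: float
    rc: float
    uninformative: bool  # g == m (parsimony-uninformative)


def site_indices(
    tree: dendropy.Tree,
    aln: Alignment,
    parts: PartitionMap | None = None,
    report: SiteReport | None = None,
    weights: dict[str, int] | None = None,
) -> list[SiteHomoplasy]:
    """Per-segregating-site homoplasy indices on the given tree.

    When the tree's tips are haplotype representatives rather than
    genomes, pass ``weights`` (tip -> genome count) so that g is computed
    on genome counts; otherwise each tip counts once.
    """
    if report is None:
        report = segregating_sites(aln)
    tips = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    missing = tips - set(aln.samples)
    if missing:
        raise ValueError(f"tree tips not in alignment: {sorted(missing)}")
    out: list[SiteHomoplasy] = []
    for rec in report.sites:
        col = aln.column(rec.position)
        states = {s: col[aln.index_of(s)] for s in tips}
        s_obs = fitch_steps(tree, states)
        # state counts over genomes (weighted tips)
        counts: dict[str, int] = {}
        for tip in tips:
            ch = states[tip]
            if ch in "ACGT":
                w = (weights or {}).get(tip, 1)
                counts[ch] = counts.get(ch, 0) + w
        m = len(counts) - 1
        total = sum(counts.values())
        g = total - max(counts.values())
        if s_obs == 0 or m == 0:
            continue  # monomorphic over the tree's tips
        ci = m / s_obs
        uninformative = g == m
        ri = 1.0 if uninformative else (g - s_obs) / (g - m)
        rc = ci * ri
        part = parts.locus_at(rec.position) if parts is not None else None
        out.append(
            SiteHomoplasy(
                position=rec.position,
                locus=part.locus if part else "other",
                locus_position=(rec.position - part.start + 1) if part else None,
                states=rec.states,
                steps=s_obs,
                min_steps=m,
                max_steps=g,
                ci=ci,
                hi=1.0 - ci,
                ri=ri,
                rc=rc,
                uninformative=uninformative,
            )
        )
    return out


def homoplasy_frame(sites: list[SiteHomoplasy]) -> pd.DataFrame:
    """Table of the per-site indices (one row per segregating site)."""
    return pd.DataFrame(
        {
            "position": [s.position for s in sites],
            "locus": [s.locus for s in sites],
            "locus_position": [s.locus_position for s in sites],
            "states": [s.states for s in sites],
            "changes": [s.steps for s in sites],
            "CI": [s.ci for s in sites],
            "HI": [s.hi for s in sites],
            "RI": [s.ri for s in sites],
            "RC": [s.rc for s in sites],
            "uninformative": [s.uninformative for s in sites],
        }
    )
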