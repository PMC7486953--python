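"""Ancestral state reconstruction of repeat abundance under Brownian motion.

Repeat abundance per cluster (in Mb per haploid genome) is treated as a
continuous trait evolving by Brownian motion (BM) on a fixed rooted tree with
branch lengths. The BM rate sigma^2 is estimated by REML via phylogenetically
independent contrasts, and ancestral node states are the best linear unbiased
predictions (BLUPs) under the BM covariance, computed with a linear-time
two-pass message-passing recursion (equivalent to GLS with the BM covariance
matrix, which the test suite verifies by explicit matrix inversion).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import dendropy
import numpy as np
import pandas as pd


class Phylogeny:
    """Rooted tree with branch lengths and deterministic node ids.

    Tips keep their taxon labels; unlabeled internal nodes are assigned ids
    ``nd<i>`` by post-order position. The branch above a node is identified by
    the node's own id (the root has no branch).
    """

    def __init__(self, tree: dendropy.Tree):
        self._children: dict[str, list[str]] = {}
        self._parent: dict[str, str | None] = {}
        self._blen: dict[str, float] = {}
        self._postorder: list[str] = []
        seen: set[str] = set()
        for node in tree.postorder_node_iter():
            nid = (node.taxon.label if node.taxon else None) or node.label
            if not nid:
                nid = f"nd{len(self._postorder)}"
            if nid in seen:
                raise ValueError(f"duplicate node label {nid!r}")
            seen.add(nid)
            node._rs_id = nid
            self._postorder.append(nid)
            self._children[nid] = [c._rs_id for c in node.child_nodes()]
            if node.parent_node is None:
                self._parent[nid] = None
                self._blen[nid] = 0.0
            else:
                bl = node.edge.length
                if bl is None or bl <= 0:
                    raise ValueError(f"branch above {nid!r} must have positive length")
                self._blen[nid] = float(bl)
        for nid, kids in self._children.items():
            for c in kids:
                self._parent[c] = nid
        self.root: str = self._postorder[-1]
        self.tips: list[str] = [n for n in self._postorder if not self._children[n]]

    @classmethod
    def from_newick(cls, newick: str) -> "Phylogeny":
        tree = dendropy.Tree.get(data=newick, schema="newick",
                                 suppress_internal_node_taxa=False)
        return cls(tree)

    @classmethod
    def from_file(cls, path) -> "Phylogeny":
        with open(path) as fh:
            return cls.from_newick(fh.read())

    # -- topology accessors -------------------------------------------------
    def postorder(self) -> list[str]:
        return list(self._postorder)

    def preorder(self) -> list[str]:
        return list(reversed(self._postorder))

    def children(self, nid: str) -> list[str]:
        return list(self._children[nid])

    def parent(self, nid: str) -> str | None:
        return self._parent[nid]

    def branch_length(self, nid: str) -> float:
        return self._blen[nid]

    def is_tip(self, nid: str) -> bool:
        return not self._children[nid]

    def branches(self) -> list[str]:
        """Branch ids (child node ids), post-order, root excluded."""
        return [n for n in self._postorder if n != self.root]

    def subtree_tips(self, nid: str) -> list[str]:
        if self.is_tip(nid):
            return [nid]
        out: list[str] = []
        stack = [nid]
        while stack:
            n = stack.pop()
            kids = self._children[n]
            if kids:
                stack.extend(kids)
            else:
                out.append(n)
        return out

    def mrca(self, tips: Iterable[str]) -> str:
        tips = set(tips)
        for nid in self._postorder:
            if tips <= set(self.subtree_tips(nid)):
                return nid
        return self.root

    def scale(self, factor: float) -> "Phylogeny":
        """Return a copy with all branch lengths multiplied by ``factor``."""
        import copy

        out = copy.deepcopy(self)
        for nid in out._blen:
            out._blen[nid] *= factor
        return out

    def root_to_node_length(self, nid: str) -> float:
        total = 0.0
        while nid != self.root:
            total += self._blen[nid]
            nid = self._parent[nid]
        return total


@dataclass
class ASRResult:
    """REML Brownian-motion reconstruction of one continuous trait."""

    trait: str
    sigma2: float
    node_states: dict[str, float]
    contrasts: list[float] = field(default_factory=list, repr=False)


def _combine(msgs: list[tuple[float, float]]) -> tuple[float, float]:
    w = sum(1.0 / v for _, v in msgs)
    m = sum(m / v for m, v in msgs) / w
    return m, 1.0 / w


def asr_bm_reml(tree: Phylogeny, tip_states: dict[str, float],
                trait: str = "trait") -> ASRResult:
    """Ancestral states and REML sigma^2 for a trait under Brownian motion.

    Down-pass: Felsenstein pruning produces, for each internal node, the
    inverse-branch-length-weighted combination of its children and one
    standardized contrast per combination step (n_tips - 1 in total).
    sigma^2_REML is the mean squared standardized contrast. Up-pass: each
    node's marginal BLUP combines the messages from all adjacent subtrees;
    the result does not depend on sigma^2.
    """
    missing = [t for t in tree.tips if t not in tip_states]
    if missing:
        raise ValueError(f"missing tip state(s): {missing}")
    n_tips = len(tree.tips)

    down: dict[str, tuple[float, float]] = {}
    contrasts: list[float] = []
    for nid in tree.postorder():
        if tree.is_tip(nid):
            down[nid] = (float(tip_states[nid]), 0.0)
            continue
        msgs = [(down[c][0], down[c][1] + tree.branch_length(c))
                for c in tree.children(nid)]
        m, v = msgs[0]
        for m2, v2 in msgs[1:]:
            contrasts.append((m - m2) / np.sqrt(v + v2))
            m, v = _combine([(m, v), (m2, v2)])
        down[nid] = (m, v)

    sigma2 = float(np.sum(np.square(contrasts)) / (n_tips - 1)) if contrasts else 0.0

    up: dict[str, tuple[float, float] | None] = {tree.root: None}
    states: dict[str, float] = {}
    for nid in tree.preorder():
        if tree.is_tip(nid):
            states[nid] = float(tip_states[nid])
            continue
        kids = tree.children(nid)
        inbound = [(down[c][0], down[c][1] + tree.branch_length(c)) for c in kids]
        if up[nid] is not None:
            inbound.append(up[nid])
        states[nid] = _combine(inbound)[0]
        for c in kids:
            msgs = [(down[s][0], down[s][1] + tree.branch_length(s))
                    for s in kids if s != c]
            if up[nid] is not None:
                msgs.append(up[nid])
            m, v = _combine(msgs)
            up[c] = (m, v + tree.branch_length(c))

    return ASRResult(trait=trait, sigma2=sigma2, node_states=states,
                     contrasts=[float(c) for c in contrasts])


def simulate_bm(tree: Phylogeny, sigma2: float, root_state: float = 0.0,
                seed: int = 0,
                jumps: dict[str, float] | None = None) -> dict[str, float]:
    """Simulate a trait under Brownian motion; returns states for all nodes.

    ``jumps`` adds a deterministic shift on named branches on top of the
    BM increment - used to plant abrupt abundance changes whose recovery by
    :func:`branch_changes` can then be scored.
    """
    rng = np.random.default_rng(seed)
    states = {tree.root: root_state}
    for nid in tree.preorder():
        if nid == tree.root:
            continue
        parent = states[tree.parent(nid)]
        v = tree.branch_length(nid)
        shift = (jumps or {}).get(nid, 0.0)
        states[nid] = parent + rng.normal(0.0, np.sqrt(sigma2 * v)) + shift
    return states


def branch_changes(result: ASRResult, tree: Phylogeny) -> pd.DataFrame:
    """Per-branch change (child state - parent state), post-order.

    For abundance traits in Mb this is the inferred gain or loss of repeat
    sequence along each branch. Along every root-to-tip path the changes
    telescope to tip state minus root state.
    """
    rows = []
    for nid in tree.branches():
        parent = tree.parent(nid)
        rows.append({
            "branch": nid,
            "parent": parent,
            "parent_state": result.node_states[parent],
            "child_state": result.node_states[nid],
            "change": result.node_states[nid] - result.node_states[parent],
        })
    return pd.DataFrame(rows)


def abundance_asr_pipeline(matrix: pd.DataFrame, tree: Phylogeny,
                           genome_sizes_pg: dict[str, float],
                           average_sexes: bool = True) -> dict[str, ASRResult]:
    """Run per-cluster BM ancestral reconstruction on an abundance matrix.

    ``matrix`` holds read proportions (clusters x samples). When
    ``average_sexes`` is set, male/female columns named ``<species>_<sex>``
    are averaged per species first; columns must then cover every tree tip.
    Proportions are converted to Mb per haploid genome before reconstruction.
    """
    from .stats import abundance_to_mb, average_sex_columns

    if average_sexes:
        matrix = average_sex_columns(matrix)
        genome_sizes_pg = _per_species_sizes(genome_sizes_pg, matrix.columns)
    mb = abundance_to_mb(matrix, genome_sizes_pg)
    missing = [t for t in tree.tips if t not in mb.columns]
    if missing:
        raise ValueError(f"tree tip(s) absent from abundance matrix: {missing}")
    results: dict[str, ASRResult] = {}
    for cluster_id, row in mb.iterrows():
        results[str(cluster_id)] = asr_bm_reml(
            tree, {t: float(row[t]) for t in tree.tips}, trait=str(cluster_id))
    return results


def _per_species_sizes(genome_sizes_pg, species_cols):
    """Collapse per-sample genome sizes to per-species means where needed."""
    out = {}
    for sp in species_cols:
        if sp in genome_sizes_pg:
            out[sp] = genome_sizes_pg[sp]
        else:
            vals = [v for k, v in genome_sizes_pg.items()
                    if k.rsplit("_", 1)[0] == sp]
            if not vals:
                raise ValueError(f"no genome size for species {sp!r}")
            out[sp] = float(np.mean(vals))
    return out
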