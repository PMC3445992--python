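"""Ancestral gene-family presence/absence reconstruction on a species tree.

Given a binary COG-style presence/absence matrix for extant species and a
rooted species tree, ancestral states are inferred per family by
parsimony and per-branch gain/loss events are read off the state changes.

Three modes:

* ``fitch`` — unit-cost parsimony (gains and losses weighted equally),
  computed by the Sankoff dynamic program;
* ``dollo`` — each family may be gained exactly once; a node is ancestrally
  present iff it lies on the minimal subtree connecting the present leaves;
* ``weighted`` — Sankoff with gain cost = ``gain_penalty`` x loss cost.
  The default penalty of 2.0 encodes that gain (which for accessory genes
  usually means lateral acquisition) is rarer than loss.

Ties at the root and in backtracking resolve toward absence: a family is
assumed gained later rather than ancestrally ubiquitous.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

GAIN = "gain"
LOSS = "loss"
MODES = ("fitch", "dollo", "weighted")

_INF = float("inf")


@dataclass
class PresenceAbsenceMatrix:
    """Binary family-by-species matrix; all-absent families are dropped."""

    family_ids: list[str]
    species_ids: list[str]
    m: np.ndarray

    def __post_init__(self):
        self.m = np.asarray(self.m, dtype=int)
        if self.m.shape != (len(self.family_ids), len(self.species_ids)):
            raise ValueError("matrix shape does not match id lists")
        if not np.isin(self.m, (0, 1)).all():
            raise ValueError("matrix entries must be 0/1")
        present = self.m.sum(axis=1) > 0
        if not present.all():
            n_drop = int((~present).sum())
            logger.warning("dropping %d all-absent families", n_drop)
            self.family_ids = [f for f, keep in zip(self.family_ids, present) if keep]
            self.m = self.m[present]

    @classmethod
    def from_tsv(cls, path) -> "PresenceAbsenceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(
            list(df.index.astype(str)), list(df.columns.astype(str)), df.to_numpy()
        )

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.m, index=self.family_ids, columns=self.species_ids).to_csv(
            path, sep="\t"
        )

    def column(self, family_id: str) -> dict[str, int]:
        i = self.family_ids.index(family_id)
        return dict(zip(self.species_ids, self.m[i]))


@dataclass
class AncestralReconstruction:
    tree: dendropy.Tree
    node_states: dict[str, frozenset]  # node label -> present families
    events: list[tuple[str, str, str]]  # (child-node label = branch, family, gain|loss)
    mode: str = "fitch"
    total_cost: float = 0.0
    per_family_cost: dict[str, float] = field(default_factory=dict)

    def events_on_branch(self, node_label: str) -> list[tuple[str, str]]:
        return [(fam, kind) for br, fam, kind in self.events if br == node_label]


def label_nodes(tree: dendropy.Tree) -> None:
    """Give every unlabeled internal node a deterministic preorder name."""
    i = 0
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            node.label = node.taxon.label
        elif not node.label:
            i += 1
            node.label = f"node_{i}"


def root_with_outgroup(tree: dendropy.Tree, outgroup_id: str) -> dendropy.Tree:
    """Root the species tree on the edge above the named outgroup leaf."""
    leaf = None
    for lf in tree.leaf_node_iter():
        if lf.taxon.label == outgroup_id:
            leaf = lf
            break
    if leaf is None:
        raise ValueError(f"outgroup {outgroup_id!r} not in tree")
    tree.reroot_at_edge(leaf.edge, update_bipartitions=False)
    tree.is_rooted = True
    return tree


def reconstruct(
    pam: PresenceAbsenceMatrix,
    tree: dendropy.Tree,
    mode: str = "fitch",
    gain_penalty: float = 2.0,
) -> AncestralReconstruction:
    """Infer ancestral presence sets and per-branch gain/loss events."""
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    if mode == "weighted" and gain_penalty <= 0:
        raise ValueError("gain_penalty must be positive")

    leaf_ids = sorted(lf.taxon.label for lf in tree.leaf_node_iter())
    if leaf_ids != sorted(pam.species_ids):
        only_tree = sorted(set(leaf_ids) - set(pam.species_ids))
        only_mat = sorted(set(pam.species_ids) - set(leaf_ids))
        raise ValueError(
            f"tree/matrix species mismatch; only in tree: {only_tree}, "
            f"only in matrix: {only_mat}"
        )
    label_nodes(tree)

    gain_cost = {"fitch": 1.0, "weighted": float(gain_penalty)}.get(mode, 1.0)
    loss_cost = 1.0

    node_present: dict[str, set] = {nd.label: set() for nd in tree.preorder_node_iter()}
    events: list[tuple[str, str, str]] = []
    per_family_cost: dict[str, float] = {}

    for fi, family in enumerate(pam.family_ids):
        leaf_state = dict(zip(pam.species_ids, pam.m[fi]))
        if mode == "dollo":
            states, cost = _dollo_states(tree, leaf_state, gain_cost, loss_cost)
        else:
            states, cost = _sankoff_states(tree, leaf_state, gain_cost, loss_cost)
        per_family_cost[family] = cost
        for node in tree.preorder_node_iter():
            if states[node.label]:
                node_present[node.label].add(family)
            parent = node.parent_node
            if parent is not None and states[parent.label] != states[node.label]:
                kind = GAIN if states[node.label] else LOSS
                events.append((node.label, family, kind))

    return AncestralReconstruction(
        tree=tree,
        node_states={k: frozenset(v) for k, v in node_present.items()},
        events=events,
        mode=mode,
        total_cost=float(sum(per_family_cost.values())),
        per_family_cost=per_family_cost,
    )


def _sankoff_states(tree, leaf_state, gain_cost, loss_cost):
    """Binary Sankoff: minimal-cost states, ties resolved toward absence."""
    cost: dict[str, list[float]] = {}

    def trans(parent_state, child_state):
        if parent_state == child_state:
            return 0.0
        return gain_cost if child_state == 1 else loss_cost

    for node in tree.postorder_node_iter():
        if node.is_leaf():
            s = leaf_state[node.taxon.label]
            cost[node.label] = [0.0 if s == 0 else _INF, 0.0 if s == 1 else _INF]
        else:
            c = [0.0, 0.0]
            for state in (0, 1):
                for child in node.child_nodes():
                    c[state] += min(
                        cost[child.label][t] + trans(state, t) for t in (0, 1)
                    )
            cost[node.label] = c

    states: dict[str, int] = {}
    root = tree.seed_node
    root_cost = cost[root.label]
    states[root.label] = 0 if root_cost[0] <= root_cost[1] else 1
    for node in tree.preorder_node_iter():
        if node is root:
            continue
        ps = states[node.parent_node.label]
        c0 = cost[node.label][0] + (loss_cost if ps == 1 else 0.0)
        c1 = cost[node.label][1] + (gain_cost if ps == 0 else 0.0)
        states[node.label] = 0 if c0 <= c1 else 1
    return states, min(root_cost)


def _dollo_states(tree, leaf_state, gain_cost, loss_cost):
    """Single-gain reconstruction: present exactly on the minimal subtree
    connecting the present leaves (their MRCA and its connecting paths)."""
    present_leaves = {lid for lid, s in leaf_state.items() if s == 1}
    if not present_leaves:
        return {nd.label: 0 for nd in tree.preorder_node_iter()}, 0.0

    has_present: dict[str, bool] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            has_present[node.label] = node.taxon.label in present_leaves
        else:
            has_present[node.label] = any(
                has_present[c.label] for c in node.child_nodes()
            )

    # MRCA of present leaves: deepest node whose subtree holds them all
    n_present = len(present_leaves)
    counts: dict[str, int] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            counts[node.label] = 1 if node.taxon.label in present_leaves else 0
        else:
            counts[node.label] = sum(counts[c.label] for c in node.child_nodes())
    mrca = tree.seed_node
    changed = True
    while changed:
        changed = False
        for child in mrca.child_nodes():
            if counts[child.label] == n_present:
                mrca = child
                changed = True
                break

    in_mrca_subtree: dict[str, bool] = {}
    for node in tree.preorder_node_iter():
        parent = node.parent_node
        if node is mrca:
            in_mrca_subtree[node.label] = True
        elif parent is None:
            in_mrca_subtree[node.label] = False
        else:
            in_mrca_subtree[node.label] = in_mrca_subtree.get(parent.label, False)

    states = {
        nd.label: int(in_mrca_subtree.get(nd.label, False) and has_present[nd.label])
        for nd in tree.preorder_node_iter()
    }
    n_loss = sum(
        1
        for nd in tree.preorder_node_iter()
        if nd.parent_node is not None
        and states[nd.parent_node.label] == 1
        and states[nd.label] == 0
    )
    return states, gain_cost + loss_cost * n_loss


def branch_diff(
    recon: AncestralReconstruction, node_a: str, node_b: str
) -> tuple[frozenset, frozenset]:
    """Families gained/lost at ``node_a`` relative to its ancestor ``node_b``."""
    nodes = {nd.label: nd for nd in recon.tree.preorder_node_iter()}
    if node_a not in nodes or node_b not in nodes:
        missing = [x for x in (node_a, node_b) if x not in nodes]
        raise KeyError(f"unknown node(s): {missing}")
    anc = nodes[node_a].parent_node
    while anc is not None and anc.label != node_b:
        anc = anc.parent_node
    if anc is None:
        raise ValueError(f"{node_b!r} is not an ancestor of {node_a!r}")
    a_set = recon.node_states[node_a]
    b_set = recon.node_states[node_b]
    return a_set - b_set, b_set - a_set


def events_table(recon: AncestralReconstruction) -> pd.DataFrame:
    return pd.DataFrame(recon.events, columns=["branch", "family", "event"])


def node_table(recon: AncestralReconstruction) -> pd.DataFrame:
    rows = [
        {"node": label, "n_families": len(fams), "families": ",".join(sorted(fams))}
        for label, fams in sorted(recon.node_states.items())
    ]
    return pd.DataFrame(rows, columns=["node", "n_families", "families"])
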