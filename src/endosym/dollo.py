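"""Dollo-parsimony gene-family dynamics on a rooted, optionally dated tree.

Under Dollo parsimony each gene family is gained exactly once — at the last
common ancestor of the taxa bearing it — and can only be lost thereafter.
The minimal-loss labeling marks a family present exactly on the union of
paths from that gain node to its bearing leaves; one loss is charged to
every branch leading from a present node into a subtree with no bearing
leaf. From the reconstruction the module derives per-branch gain/loss
counts, per-node family totals, the retained fraction of an ancestral
inventory, piecewise loss-rate timelines over node ages, and pairwise
shared-family tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .simulate import load_dated_tree, node_ages, _label


@dataclass
class PresenceAbsenceMatrix:
    """Binary families × taxa matrix; taxa must match tree leaf labels."""

    data: pd.DataFrame  # index: family ids, columns: taxon ids, values 0/1

    def __post_init__(self) -> None:
        vals = self.data.to_numpy()
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("matrix entries must be 0 or 1")
        empty = self.data.index[self.data.sum(axis=1) == 0]
        if len(empty):
            raise ValueError(
                f"families absent from every taxon: {list(empty[:5])}"
            )

    @property
    def families(self) -> list:
        return list(self.data.index)

    @property
    def taxa(self) -> list:
        return list(self.data.columns)

    def filter_min_taxa(self, k: int) -> "PresenceAbsenceMatrix":
        """Optional preprocessing filter: keep families in ≥ k taxa."""
        return PresenceAbsenceMatrix(self.data[self.data.sum(axis=1) >= k])

    @classmethod
    def from_tsv(cls, path) -> "PresenceAbsenceMatrix":
        return cls(pd.read_csv(path, sep="\t", index_col=0))

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t")

    @classmethod
    def from_presence(cls, presence: dict, taxa: list) -> "PresenceAbsenceMatrix":
        """Build from {taxon: iterable of family ids} (e.g. a truth log)."""
        fams = sorted({f for t in taxa for f in presence[t]})
        data = pd.DataFrame(
            [[1 if f in set(presence[t]) else 0 for t in taxa] for f in fams],
            index=fams,
            columns=taxa,
        )
        return cls(data)


@dataclass
class DolloReconstruction:
    node_families: dict  # node label -> frozenset of families
    gains: dict  # branch (child-node label) -> list of families gained
    losses: dict  # branch -> list of families lost
    tree: dendropy.Tree

    def node_counts(self) -> dict:
        return {k: len(v) for k, v in self.node_families.items()}

    def branch_table(self) -> pd.DataFrame:
        rows = []
        for br in self.gains:
            rows.append(
                {
                    "branch": br,
                    "gains": len(self.gains[br]),
                    "losses": len(self.losses[br]),
                    "families": len(self.node_families[br]),
                }
            )
        return pd.DataFrame(rows)

    def total_losses(self) -> int:
        return sum(len(v) for v in self.losses.values())


def dollo_reconstruct(
    matrix: PresenceAbsenceMatrix, tree: dendropy.Tree | str
) -> DolloReconstruction:
    """Minimal-loss Dollo labeling of every family on a rooted tree."""
    if isinstance(tree, str):
        tree = load_dated_tree(tree)
    if tree.seed_node is None or len(tree.seed_node.child_nodes()) < 2:
        raise ValueError("tree must be rooted with ≥2 root children")
    leaf_labels = {_label(l) for l in tree.leaf_node_iter()}
    missing = set(matrix.taxa) - leaf_labels
    if missing:
        raise ValueError(f"matrix taxa not on tree: {sorted(missing)}")

    # per-node bearing-leaf sets (postorder)
    bearing: dict[str, set] = {}
    for nd in tree.postorder_node_iter():
        lab = _label(nd)
        if nd.is_leaf():
            if lab in matrix.taxa:
                col = matrix.data[lab]
                bearing[lab] = set(col.index[col == 1])
            else:
                bearing[lab] = set()
        else:
            s: set = set()
            for ch in nd.child_nodes():
                s |= bearing[_label(ch)]
            bearing[lab] = s

    # gain node per family = LCA of bearing leaves = shallowest node whose
    # bearing set contains the family and whose parent's subtree adds nothing
    # — equivalently: present(node) iff family in bearing(node) and node is
    # within the gain subtree. Compute gain node as the node where the family
    # first appears on the path down (preorder).
    node_families: dict[str, set] = {}
    gains: dict[str, list] = {}
    losses: dict[str, list] = {}
    for nd in tree.preorder_node_iter():
        lab = _label(nd)
        if nd.parent_node is None:
            # root: present iff >=2 children subtrees bear it (LCA at root)
            # or all bearing leaves are below the root anyway: the gain node
            # of family f is the LCA; root holds f iff LCA(f) == root.
            child_sets = [bearing[_label(c)] for c in nd.child_nodes()]
            present = set()
            for f in bearing[lab]:
                k = sum(1 for cs in child_sets if f in cs)
                if k >= 2:
                    present.add(f)
            node_families[lab] = present
            gains[lab] = sorted(present)  # families gained at/above the root
            losses[lab] = []
        else:
            parent = node_families[_label(nd.parent_node)]
            present = {f for f in bearing[lab] if f in parent}
            gained = set()
            for f in bearing[lab] - parent:
                # gained on this branch iff this node is the family's LCA:
                # i.e. the family does not appear anywhere outside this subtree
                # and (leaf, or >=2 children bear it)
                if nd.is_leaf():
                    gained.add(f)
                else:
                    k = sum(1 for c in nd.child_nodes() if f in bearing[_label(c)])
                    if k >= 2:
                        gained.add(f)
            # families bearing below but gained deeper are not yet present
            present |= gained
            lost = sorted(parent - set(bearing[lab]) - present)
            node_families[lab] = present
            gains[lab] = sorted(gained)
            losses[lab] = [f for f in lost]
            # note: f in parent but absent from every leaf below → one loss
            # charged on this branch (minimal Dollo)
    node_families = {k: frozenset(v) for k, v in node_families.items()}
    return DolloReconstruction(node_families, gains, losses, tree)


def retained_fraction(retained: int, lost: int) -> float:
    """Percentage of an ancestral inventory still present: 100·r/(r+l)."""
    if retained < 0 or lost < 0:
        raise ValueError("counts must be non-negative")
    if retained + lost == 0:
        raise ValueError("retained and lost cannot both be zero")
    return 100.0 * retained / (retained + lost)


@dataclass
class LossTimeline:
    leaf: str
    intervals: list  # (age_start, age_end, families_lost, rate_per_my)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.intervals,
            columns=["age_start", "age_end", "families_lost", "rate_per_my"],
        )


def loss_timeline(
    recon: DolloReconstruction, ages: dict | None = None, leaf: str | None = None
) -> dict:
    """Per-branch loss intervals along each root-to-leaf path.

    ``ages`` maps node labels to ages in Mya (default: derived from the
    reconstruction's tree branch lengths, leaves at age 0). Returns
    {leaf label: LossTimeline}; each interval is one branch, with
    rate = families lost / branch duration in My.
    """
    tree = recon.tree
    if ages is None:
        ages = node_ages(tree)
    out = {}
    for lf in tree.leaf_node_iter():
        lab = _label(lf)
        if leaf is not None and lab != leaf:
            continue
        path = []
        nd = lf
        while nd.parent_node is not None:
            path.append(nd)
            nd = nd.parent_node
        intervals = []
        for nd in reversed(path):
            child_l = _label(nd)
            parent_l = _label(nd.parent_node)
            if parent_l not in ages or child_l not in ages:
                raise ValueError(f"undated node on path to {lab}")
            a0, a1 = ages[parent_l], ages[child_l]
            lost = len(recon.losses[child_l])
            dur = a0 - a1
            rate = lost / dur if dur > 0 else 0.0
            intervals.append((a0, a1, lost, rate))
        out[lab] = LossTimeline(lab, intervals)
    return out if leaf is None else out[leaf]


def shared_family_counts(
    matrix: PresenceAbsenceMatrix, taxon_pairs: list
) -> pd.DataFrame:
    """|intersection|, |union| and Jaccard for each requested taxon pair."""
    rows = []
    for a, b in taxon_pairs:
        for t in (a, b):
            if t not in matrix.taxa:
                raise KeyError(f"unknown taxon {t!r}")
        sa = set(matrix.data.index[matrix.data[a] == 1])
        sb = set(matrix.data.index[matrix.data[b] == 1])
        inter, union = len(sa & sb), len(sa | sb)
        rows.append(
            {
                "taxon_a": a,
                "taxon_b": b,
                "shared": inter,
                "union": union,
                "jaccard": inter / union if union else float("nan"),
            }
        )
    return pd.DataFrame(rows)
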