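"""Synteny blocks, DCJ genomic distance, and inversion parsimony on a tree.

Shared single-copy gene orders are collapsed into maximal collinear synteny
blocks (runs of genes whose oriented adjacencies are conserved in every
genome); each genome then becomes a signed permutation of the common block
universe. The double-cut-and-join (DCJ) distance between two such
permutations is N − C for circular genomes (blocks minus adjacency-graph
cycles), the minimum number of DCJ operations — inversions, fissions,
fusions — transforming one into the other. Inversion events are assigned to
tree branches by parsimony against an ancestral (outgroup-derived) block
order.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy

from .genome import AnnotatedGenome
from .simulate import load_dated_tree, _label


@dataclass
class SignedBlockOrder:
    """Circular (or linear) signed permutation of synteny blocks."""

    genome: str
    order: tuple  # signed non-zero ints, e.g. (1, -3, 2)
    circular: bool = True

    def __post_init__(self) -> None:
        self.order = tuple(int(b) for b in self.order)
        ids = [abs(b) for b in self.order]
        if len(ids) != len(set(ids)):
            raise ValueError("each block must appear exactly once")
        if 0 in ids:
            raise ValueError("block ids must be non-zero")

    @property
    def universe(self) -> frozenset:
        return frozenset(abs(b) for b in self.order)


def _adjacencies(order: SignedBlockOrder) -> tuple:
    """Adjacency set over block extremities; telomeres for linear genomes.

    Extremity encoding: (block, "t") tail / (block, "h") head; a block
    traversed as +b contributes tail→head.
    """
    ext = []
    for b in order.order:
        if b > 0:
            ext.append(((b, "t"), (b, "h")))
        else:
            ext.append(((-b, "h"), (-b, "t")))
    adjs = []
    for i in range(len(ext) - 1):
        adjs.append(frozenset((ext[i][1], ext[i + 1][0])))
    telomeres = []
    if order.circular and len(ext) > 0:
        adjs.append(frozenset((ext[-1][1], ext[0][0])))
    elif ext:
        telomeres = [ext[0][0], ext[-1][1]]
    return adjs, telomeres


def dcj_distance(a: SignedBlockOrder, b: SignedBlockOrder) -> int:
    """Minimum number of DCJ operations transforming ``a`` into ``b``.

    For two circular genomes this is N − C where C is the number of cycles
    in the adjacency graph; linear genomes add odd paths: N − (C + I/2).
    """
    if a.universe != b.universe:
        raise ValueError("block universes differ")
    if a.circular != b.circular:
        raise ValueError("genomes must both be circular or both linear")
    n = len(a.order)
    adj_a, tel_a = _adjacencies(a)
    adj_b, tel_b = _adjacencies(b)
    # graph on extremities: edges = adjacencies from both genomes
    neigh: dict = {}
    for adj in adj_a + adj_b:
        items = tuple(adj)
        if len(items) == 1:  # self-adjacency of a single-block circle
            x = items[0]
            neigh.setdefault(x, []).append(x)
            neigh.setdefault(x, [])
        else:
            x, y = items
            neigh.setdefault(x, []).append(y)
            neigh.setdefault(y, []).append(x)
    for t in tel_a + tel_b:
        neigh.setdefault(t, [])
    seen = set()
    cycles = odd_paths = 0
    for start in list(neigh):
        if start in seen:
            continue
        # walk the component
        comp_nodes = set()
        stack = [start]
        edges = 0
        while stack:
            v = stack.pop()
            if v in comp_nodes:
                continue
            comp_nodes.add(v)
            for w in neigh[v]:
                stack.append(w)
        seen |= comp_nodes
        deg = {v: len(neigh[v]) for v in comp_nodes}
        edges = sum(deg.values()) // 2
        # self-loop counts twice in adjacency list? handle: a == b case
        n_ends = sum(1 for v in comp_nodes if deg[v] == 1)
        if n_ends == 0:
            cycles += 1
        elif edges % 2 == 1:
            odd_paths += 1
    return n - cycles - odd_paths // 2


# --------------------------------------------------------- block derivation


def single_copy_gene_orders(genomes: list) -> dict:
    """Ordered signed gene-family lists restricted to families single-copy
    and intact (non-pseudogene) in *every* genome. Duplicated families are
    excluded — they mark candidate breakpoints rather than block interiors.
    """
    per_genome = {}
    for g in genomes:
        fams: dict[str, list] = {}
        for f in sorted(g.features, key=lambda f: f.start):
            if f.kind == "pseudogene":
                continue
            fams.setdefault(f.family or f.id, []).append(f)
        per_genome[g.id] = fams
    shared = None
    for fams in per_genome.values():
        single = {k for k, v in fams.items() if len(v) == 1}
        shared = single if shared is None else shared & single
    orders = {}
    for g in genomes:
        feats = [
            (fam, fs[0]) for fam, fs in per_genome[g.id].items() if fam in shared
        ]
        feats.sort(key=lambda t: t[1].start)
        orders[g.id] = [(fam, f.strand) for fam, f in feats]
    return orders


def duplicated_gene_positions(genome: AnnotatedGenome) -> list:
    """Loci of multi-copy families — candidate inversion breakpoints."""
    fams: dict[str, list] = {}
    for f in genome.features:
        fams.setdefault(f.family or f.id, []).append(f)
    out = []
    for fam, fs in fams.items():
        if len(fs) > 1:
            out.extend((fam, f.start, f.end) for f in fs)
    return sorted(out, key=lambda t: t[1])


def _oriented_adjacency(a, sa, b, sb):
    """Canonical form of the oriented adjacency a(sa) → b(sb)."""
    fwd = (a, sa, b, sb)
    rev = (b, -sb, a, -sa)
    return min(fwd, rev)


def blocks_from_gene_orders(
    gene_orders: dict, circular: bool = True, min_block_genes: int = 1
) -> dict:
    """Collapse shared gene orders into signed synteny-block permutations.

    A gene adjacency survives iff its oriented form appears in every genome
    (allowing whole-strand reversal); maximal runs of surviving adjacencies
    in the reference (first) genome become blocks. Blocks with fewer than
    ``min_block_genes`` genes are dropped from the permutation and the
    blocks recomputed on the remaining genes.
    """
    ids = list(gene_orders)
    if len(ids) < 2:
        raise ValueError("need at least two genomes")
    ref = ids[0]
    genes_ref = [g for g, _ in gene_orders[ref]]
    if len(genes_ref) < 2:
        raise ValueError("fewer than 2 shared single-copy genes")
    for gid in ids[1:]:
        if sorted(g for g, _ in gene_orders[gid]) != sorted(genes_ref):
            raise ValueError("genomes must share the same gene set")

    def adjacency_set(order):
        pairs = set()
        seq = list(order)
        rng = range(len(seq)) if circular else range(len(seq) - 1)
        for i in rng:
            (a, sa), (b, sb) = seq[i], seq[(i + 1) % len(seq)]
            pairs.add(_oriented_adjacency(a, sa, b, sb))
        return pairs

    conserved = None
    for gid in ids:
        s = adjacency_set(gene_orders[gid])
        conserved = s if conserved is None else conserved & s

    # break the reference order wherever its adjacency is not conserved
    ref_order = list(gene_orders[ref])
    nref = len(ref_order)
    breaks = []
    rng = range(nref) if circular else range(nref - 1)
    for i in rng:
        (a, sa), (b, sb) = ref_order[i], ref_order[(i + 1) % nref]
        if _oriented_adjacency(a, sa, b, sb) not in conserved:
            breaks.append((i + 1) % nref)
    if not breaks:  # fully collinear: a single block everywhere
        block_of = {g: (1, i, s) for i, (g, s) in enumerate(ref_order)}
        n_blocks = 1
    else:
        start = breaks[0] if circular else 0
        rotated = ref_order[start:] + ref_order[:start] if circular else ref_order
        cuts = sorted(((b - start) % nref) for b in breaks) if circular else breaks
        if not circular:
            cuts = [0] + [c for c in cuts if c > 0] + [nref]
        else:
            cuts = [0] + [c for c in cuts if c > 0] + [nref]
        block_of = {}
        n_blocks = 0
        for bi in range(len(cuts) - 1):
            seg = rotated[cuts[bi] : cuts[bi + 1]]
            if not seg:
                continue
            n_blocks += 1
            for pos, (g, s) in enumerate(seg):
                block_of[g] = (n_blocks, pos, s)

    if min_block_genes > 1:
        sizes: dict[int, int] = {}
        for b, _, _ in block_of.values():
            sizes[b] = sizes.get(b, 0) + 1
        keep = {g for g, (b, _, _) in block_of.items() if sizes[b] >= min_block_genes}
        if len(keep) < 2:
            raise ValueError("fewer than 2 genes after block-size filtering")
        filtered = {
            gid: [(g, s) for g, s in order if g in keep]
            for gid, order in gene_orders.items()
        }
        return blocks_from_gene_orders(filtered, circular=circular, min_block_genes=1)

    out = {}
    for gid in ids:
        blocks = []
        for g, s in gene_orders[gid]:
            b, pos, sref = block_of[g]
            orient = 1 if s == sref else -1
            if blocks and abs(blocks[-1]) == b:
                continue
            blocks.append(orient * b)
        # circular: the same block may open and close the list
        if circular and len(blocks) > 1 and abs(blocks[0]) == abs(blocks[-1]):
            blocks.pop()
        out[gid] = SignedBlockOrder(gid, tuple(blocks), circular=circular)
    universe = out[ref].universe
    for gid in ids:
        if out[gid].universe != universe:
            raise ValueError(f"genome {gid} does not cover all blocks")
    return out


# ----------------------------------------------------------- tree parsimony


def tree_inversion_parsimony(
    orders: dict,
    tree: dendropy.Tree | str,
    ancestral_order: SignedBlockOrder,
) -> dict:
    """Assign rearrangement events to branches by parsimony.

    Internal-node orders are chosen greedily from the candidate set
    {children's assigned orders, the ancestral order}, minimizing the local
    sum of DCJ distances — exact for a star topology with a supplied
    ancestor, a heuristic on deeper trees. Branch counts are DCJ distances
    between the assigned parent and child orders.
    """
    if isinstance(tree, str):
        tree = load_dated_tree(tree)
    universe = ancestral_order.universe
    for gid, o in orders.items():
        if o.universe != universe:
            raise ValueError(f"order for {gid} is over a different block universe")
    assigned: dict[str, SignedBlockOrder] = {}
    for nd in tree.postorder_node_iter():
        lab = _label(nd)
        if nd.is_leaf():
            if lab not in orders:
                raise KeyError(f"no block order for leaf {lab}")
            assigned[lab] = orders[lab]
        else:
            cands = [assigned[_label(c)] for c in nd.child_nodes()]
            cands.append(ancestral_order)
            best = min(
                cands,
                key=lambda cand: sum(
                    dcj_distance(cand, assigned[_label(c)]) for c in nd.child_nodes()
                )
                + dcj_distance(cand, ancestral_order),
            )
            assigned[lab] = best
    root_lab = _label(tree.seed_node)
    assigned[root_lab] = ancestral_order
    per_branch = {}
    for nd in tree.preorder_node_iter():
        if nd.parent_node is None:
            continue
        lab = _label(nd)
        per_branch[lab] = dcj_distance(assigned[_label(nd.parent_node)], assigned[lab])
    return {
        "per_branch": per_branch,
        "total": sum(per_branch.values()),
        "assigned": assigned,
    }
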