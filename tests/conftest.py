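"""Shared fixtures: small simulated genomes and truth-tracking helpers."""

from __future__ import annotations

import numpy as np
import pytest

from endosym import (
    AncestorSpec,
    EvolutionParams,
    align_pair,
    evolve_tree,
    generate_ancestor,
    load_dated_tree,
    project_threeway,
)
from endosym.genome import revcomp


@pytest.fixture(scope="session")
def small_ancestor():
    spec = AncestorSpec(
        genome_length=30_000,
        n_genes=24,
        gc_content=0.40,
        mean_cds_length=700,
        n_duplicated_genes=2,
        rng_seed=42,
    )
    return generate_ancestor(spec)


@pytest.fixture(scope="session")
def strain_trio(small_ancestor):
    """Three strains + truth log under the default strain scenario."""
    params = EvolutionParams(
        seed=7,
        indel_rate=2e-5,
        gene_loss_rate_per_phase=(),
        inversion_rate=0.0,
    )
    leaves, log = evolve_tree(small_ancestor, params)
    return small_ancestor, params, leaves, log


@pytest.fixture(scope="session")
def trio_threeway(strain_trio):
    anc, params, leaves, log = strain_trio
    a1 = align_pair(leaves["KR01"], leaves["NZ27"])
    a2 = align_pair(leaves["FK01"], leaves["NZ27"])
    return project_threeway(a1, a2, "NZ27")


def apply_events_with_tags(anc_seq: str, events):
    """Replay logged events on (sequence, ancestor-position tags).

    Independent coordinate-tracking oracle: each current position carries
    the index of the ancestral base it descends from (None for inserted
    bases), so true variant sets can be expressed in ancestor coordinates.
    """
    seq = list(anc_seq)
    tags: list = list(range(len(anc_seq)))
    for ev in events:
        if ev.etype == "sub":
            assert seq[ev.position] == ev.from_base
            seq[ev.position] = ev.to_base
        elif ev.etype == "indel":
            if ev.kind == "ins":
                seq[ev.position : ev.position] = list(ev.seq)
                tags[ev.position : ev.position] = [None] * ev.length
            else:
                del seq[ev.position : ev.position + ev.length]
                del tags[ev.position : ev.position + ev.length]
        elif ev.etype == "loss":
            if ev.mode == "pseudogenization":
                for p, frm, to in ev.spans:
                    seq[p] = to
            else:
                for pos, dseq in ev.spans:
                    del seq[pos : pos + len(dseq)]
                    del tags[pos : pos + len(dseq)]
        elif ev.etype == "inversion":
            seq[ev.start : ev.end] = list(revcomp("".join(seq[ev.start : ev.end])))
            tags[ev.start : ev.end] = [None] * (ev.end - ev.start)
        else:
            raise AssertionError(ev.etype)
    return "".join(seq), tags


def path_events(log, tree, leaf: str):
    """Events along the root→leaf path, in application order."""
    node = next(l for l in tree.leaf_node_iter() if l.taxon.label == leaf)
    labels = []
    while node.parent_node is not None:
        lab = node.taxon.label if node.taxon else node.label
        labels.append(lab)
        node = node.parent_node
    out = []
    for lab in reversed(labels):
        out.extend(log.by_branch(lab))
    return out


def true_variant_sets(anc_seq: str, log, tree, leaf: str):
    """True SNP positions (ancestor coords) and indel lengths for a leaf."""
    seq, tags = apply_events_with_tags(anc_seq, path_events(log, tree, leaf))
    snps = {
        tags[j]
        for j, ch in enumerate(seq)
        if tags[j] is not None and anc_seq[tags[j]] != ch
    }
    # deletions: maximal runs of ancestor positions absent from tags
    present = sorted(t for t in tags if t is not None)
    deleted = sorted(set(range(len(anc_seq))) - set(present))
    del_lengths = []
    run = 0
    prev = None
    for p in deleted:
        if prev is not None and p == prev + 1:
            run += 1
        else:
            if run:
                del_lengths.append(run)
            run = 1
        prev = p
    if run:
        del_lengths.append(run)
    # insertions: maximal runs of None tags
    ins_lengths = []
    run = 0
    for t in tags:
        if t is None:
            run += 1
        elif run:
            ins_lengths.append(run)
            run = 0
    if run:
        ins_lengths.append(run)
    return snps, sorted(del_lengths), sorted(ins_lengths)
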