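"""Truth-logged genome-evolution simulator for reductive endosymbiont genomes.

Generates an ancestral annotated genome and evolves it along a rooted dated
tree (branch lengths in My) under four processes:

* **substitutions** — a per-site 4-state continuous-time Markov chain whose
  directed rates come from six collapsed, strand-complementary class weights
  (e.g. G:C→A:T transitions). Simulated exactly by uniformization: Poisson
  proposals at the maximum per-site rate, thinned by the current base's
  actual leaving rate. With uniform class weights every site leaves at rate
  ``sub_rate`` exactly, so branch counts are Poisson(sub_rate · t · L).
* **indels** — per-site rate ``indel_rate × slippage_multiplier^(run−1)``
  where *run* is the length of the mononucleotide run containing the site,
  emulating replication slippage; lengths drawn from a four-class mixture
  (1 bp, 2–15, 16–42, 97–136 bp) patterned on observed chromatophore indel
  size spectra. Coding positions are thinned by ``cds_indel_factor``.
* **gene losses** — per-family exponential waiting times with a piecewise
  (two-phase) rate over node ages, Dollo-compatible by construction (a lost
  family is never re-gained). A loss either deletes the locus outright or
  pseudogenizes it (premature stop codon), per ``pseudogenization_prob``.
* **inversions** — segment reversals whose breakpoints fall preferentially
  between duplicated-gene pairs (repeat-mediated recombination), otherwise
  at intergenic positions; breakpoints never split a feature.

Every event is appended to a :class:`TruthLog`; replaying the log on the
ancestor reproduces each leaf byte-exactly, which is the backbone of the
parameter-recovery tests.

Randomness: one ``numpy.random.Generator`` seeded from ``rng_seed`` /
``seed`` drives all stages sequentially in a fixed preorder traversal of the
tree, so a single seed makes the whole simulation reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Sequence

import dendropy
import numpy as np

from .genome import AnnotatedGenome, Feature, revcomp

# Collapsed, strand-symmetric substitution classes. Each covers the directed
# change shown and its complement (A→G pairs with T→C, etc.).
SPECTRUM_CLASSES = ("A>G", "A>C", "A>T", "G>A", "G>T", "G>C")
_CLASS_OF = {}
for _i, _c in enumerate(SPECTRUM_CLASSES):
    _x, _y = _c.split(">")
    _COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}
    _CLASS_OF[(_x, _y)] = _i
    _CLASS_OF[(_COMP[_x], _COMP[_y])] = _i

STOP_CODONS = {"TAA", "TAG", "TGA"}

# Default AT-biased spectrum: transitions dominate and G:C→A:T runs at about
# twice the A:T→G:C rate, giving an equilibrium GC near 1/3.
DEFAULT_SPECTRUM = {
    "A>G": 0.18,
    "A>C": 0.05,
    "A>T": 0.09,
    "G>A": 0.40,
    "G>T": 0.08,
    "G>C": 0.20,
}

# Indel length mixture: (lo, hi) bp per class, observed-count weights.
INDEL_CLASSES = ((1, 1), (2, 15), (16, 42), (97, 136))
DEFAULT_INDEL_CLASS_WEIGHTS = (138 / 211, 55 / 211, 14 / 211, 4 / 211)
DEFAULT_INSERTION_PROB = (0.5, 0.5, 0.2, 0.0)


@dataclass
class AncestorSpec:
    """Parameters of the simulated ancestral genome.

    Defaults emulate a ~1 Mb chromatophore-like genome at 40% GC with ~860
    CDS and a pair of duplicated genes usable as inversion breakpoints.
    """

    genome_length: int = 1_000_000
    n_genes: int = 860
    gc_content: float = 0.40
    mean_cds_length: int = 950
    intergenic_fraction: float = 0.15
    n_duplicated_genes: int = 2
    rng_seed: int = 0

    def validate(self) -> None:
        if self.genome_length <= 0:
            raise ValueError("genome_length must be positive")
        if not 0 < self.gc_content < 1:
            raise ValueError("gc_content must lie in (0, 1)")
        if self.n_genes * self.mean_cds_length > self.genome_length:
            raise ValueError(
                "infeasible packing: n_genes × mean_cds_length exceeds genome_length"
            )
        if self.n_duplicated_genes * 2 > self.n_genes:
            raise ValueError("more duplicate pairs than genes")


@dataclass
class EvolutionParams:
    """Rates and distributions governing evolution along the tree.

    Rates are per My; the tree's branch lengths must be in My. The default
    rates reproduce chromatophore-scale divergence: with coding sites thinned
    by ``cds_sub_factor`` over ~84% of the genome, 3.7e-3 subs/site/My over a
    10 My leaf-to-leaf path gives ~23 SNPs/kb genome-wide between strains.
    """

    tree: str = "((KR01:2.5,FK01:2.5)KF:2.5,NZ27:5.0)R;"
    sub_rate: float = 3.7e-3  # substitutions/site/My (uniform-weight scale)
    spectrum: dict = field(default_factory=lambda: dict(DEFAULT_SPECTRUM))
    indel_rate: float = 1.5e-5  # events/site/My at run length 1
    indel_class_weights: tuple = DEFAULT_INDEL_CLASS_WEIGHTS
    insertion_prob: tuple = DEFAULT_INSERTION_PROB
    slippage_multiplier: float = 1.8  # per extra bp of homopolymer run
    slippage_run_cap: int = 12
    cds_sub_factor: float = 0.55  # substitution thinning inside features
    cds_indel_factor: float = 0.025  # indel thinning inside features
    gene_loss_rate_per_phase: tuple = ((124.0, 60.0, 0.0162), (60.0, 0.0, 8.1e-4))
    # Inversions are a species-scale process; among near-identical strains
    # (the default tree) genome structure is conserved, so the default is 0.
    # Species-level scenarios set a positive rate (see docs/methods.md).
    inversion_rate: float = 0.0  # events/My/genome
    pseudogenization_prob: float = 0.5
    dup_breakpoint_prob: float = 0.8
    seed: int = 0

    def validate(self) -> None:
        for name in ("sub_rate", "indel_rate", "inversion_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be ≥ 0")
        w = sum(self.spectrum.get(c, 0.0) for c in SPECTRUM_CLASSES)
        if abs(w - 1.0) > 1e-9:
            raise ValueError("spectrum weights must sum to 1")
        for a0, a1, r in self.gene_loss_rate_per_phase:
            if r < 0 or a0 < a1:
                raise ValueError("loss phases need age_start ≥ age_end and rate ≥ 0")

    def directed_rates(self) -> dict:
        """Per-site directed rates q(X→Y) implied by the class weights."""
        q = {}
        for (x, y), ci in _CLASS_OF.items():
            q[(x, y)] = self.sub_rate * 2.0 * self.spectrum[SPECTRUM_CLASSES[ci]]
        return q


# ------------------------------------------------------------------ events


@dataclass
class SubEvent:
    etype: str
    branch: str
    position: int
    from_base: str
    to_base: str


@dataclass
class IndelEvent:
    etype: str
    branch: str
    position: int
    length: int
    kind: str  # "ins" | "del"
    seq: str
    run_length: int  # mononucleotide run context at application time
    region: str  # "coding" | "noncoding" at application time


@dataclass
class LossEvent:
    etype: str
    branch: str
    family: str
    mode: str  # "deletion" | "pseudogenization"
    spans: list  # deletion: [(pos, deleted_seq)]; pseudo: [(pos, from, to)]


@dataclass
class InversionEvent:
    etype: str
    branch: str
    start: int
    end: int


@dataclass
class TruthLog:
    """Ordered per-branch event log plus true per-node family presence."""

    events: list = field(default_factory=list)
    presence: dict = field(default_factory=dict)  # node label -> sorted family list

    def by_branch(self, branch: str) -> list:
        return [e for e in self.events if e.branch == branch]

    def substitutions(self, branch: str | None = None) -> list:
        return [
            e
            for e in self.events
            if e.etype == "sub" and (branch is None or e.branch == branch)
        ]

    def indels(self, branch: str | None = None) -> list:
        return [
            e
            for e in self.events
            if e.etype == "indel" and (branch is None or e.branch == branch)
        ]

    def losses(self, branch: str | None = None) -> list:
        return [
            e
            for e in self.events
            if e.etype == "loss" and (branch is None or e.branch == branch)
        ]

    def inversions(self, branch: str | None = None) -> list:
        return [
            e
            for e in self.events
            if e.etype == "inversion" and (branch is None or e.branch == branch)
        ]

    def write_jsonl(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(json.dumps({"presence": self.presence}) + "\n")
            for e in self.events:
                fh.write(json.dumps(asdict(e)) + "\n")

    @classmethod
    def read_jsonl(cls, path: str | Path) -> "TruthLog":
        log = cls()
        with open(path) as fh:
            header = json.loads(fh.readline())
            log.presence = header["presence"]
            classes = {
                "sub": SubEvent,
                "indel": IndelEvent,
                "loss": LossEvent,
                "inversion": InversionEvent,
            }
            for line in fh:
                d = json.loads(line)
                ev = classes[d["etype"]](**d)
                if ev.etype == "loss":
                    ev.spans = [tuple(s) for s in ev.spans]
                log.events.append(ev)
        return log


# ------------------------------------------------------- ancestor synthesis


def _random_codon(rng: np.random.Generator, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    bases = "ACGT"
    while True:
        codon = "".join(bases[i] for i in rng.choice(4, size=3, p=p))
        if codon not in STOP_CODONS and codon != "ATG":
            return codon


def _random_seq(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=n, p=p)])


def generate_ancestor(spec: AncestorSpec) -> AnnotatedGenome:
    """Build a circular annotated ancestor matching ``spec``.

    CDS are non-overlapping, strand-randomized, start with ATG and end with
    a stop codon; the last ``n_duplicated_genes`` gene slots carry exact
    copies of earlier genes (same family label). Realized GC is corrected to
    within ±0.2% of target by flipping intergenic bases, comfortably inside
    the ±1% contract.
    """
    spec.validate()
    rng = np.random.default_rng(spec.rng_seed)

    # CDS lengths: multiples of 3, mildly dispersed around the mean.
    min_len = 30
    raw = rng.normal(spec.mean_cds_length, spec.mean_cds_length / 5, spec.n_genes)
    lengths = np.maximum(min_len, (np.round(raw / 3) * 3).astype(int))
    # Shrink uniformly if packing would overflow the target coding share.
    budget = int(spec.genome_length * (1 - min(spec.intergenic_fraction, 0.9)))
    budget = max(budget, spec.n_genes * min_len)
    while lengths.sum() > min(budget, spec.genome_length - spec.n_genes):
        lengths = np.maximum(min_len, ((lengths * 0.95) // 3 * 3).astype(int))

    # Duplicate pairs: final slots mirror early genes (length + sequence).
    n_dup = spec.n_duplicated_genes
    dup_sources = list(range(n_dup))
    for k in range(n_dup):
        lengths[spec.n_genes - n_dup + k] = lengths[dup_sources[k]]

    total_gap = spec.genome_length - int(lengths.sum())
    # One gap before each gene (circular: the first gap keeps position 0
    # feature-free so nothing wraps the origin).
    gaps = rng.multinomial(total_gap - spec.n_genes, [1 / spec.n_genes] * spec.n_genes)
    gaps = gaps + 1

    gene_seqs: list[str] = []
    for i in range(spec.n_genes):
        if i >= spec.n_genes - n_dup:
            gene_seqs.append(gene_seqs[dup_sources[i - (spec.n_genes - n_dup)]])
            continue
        n_codons = lengths[i] // 3
        body = "".join(
            _random_codon(rng, spec.gc_content) for _ in range(n_codons - 2)
        )
        stop = ("TAA", "TAG", "TGA")[rng.integers(3)]
        gene_seqs.append("ATG" + body + stop)

    parts: list[str] = []
    features: list[Feature] = []
    pos = 0
    for i in range(spec.n_genes):
        parts.append(_random_seq(rng, int(gaps[i]), spec.gc_content))
        pos += int(gaps[i])
        strand = 1 if rng.random() < 0.5 else -1
        placed = gene_seqs[i] if strand == 1 else revcomp(gene_seqs[i])
        parts.append(placed)
        if i >= spec.n_genes - n_dup:
            fam = f"fam{dup_sources[i - (spec.n_genes - n_dup)]:04d}"
        else:
            fam = f"fam{i:04d}"
        features.append(
            Feature(
                id=f"g{i:04d}",
                kind="CDS",
                start=pos,
                end=pos + len(placed),
                strand=strand,
                family=fam,
            )
        )
        pos += len(placed)
    seq = list("".join(parts))
    assert len(seq) == spec.genome_length

    # GC correction on intergenic positions only.
    coding = np.zeros(len(seq), dtype=bool)
    for f in features:
        coding[f.start : f.end] = True
    intergenic_idx = np.flatnonzero(~coding)
    arr = np.array(seq)
    gc_now = np.isin(arr, ["G", "C"]).sum() / len(arr)
    tol = 0.002
    if abs(gc_now - spec.gc_content) > tol and len(intergenic_idx):
        need = int(round((spec.gc_content - gc_now) * len(arr)))
        if need > 0:
            cand = intergenic_idx[np.isin(arr[intergenic_idx], ["A", "T"])]
            pick = rng.choice(cand, size=min(need, len(cand)), replace=False)
            arr[pick] = rng.choice(["G", "C"], size=len(pick))
        else:
            cand = intergenic_idx[np.isin(arr[intergenic_idx], ["G", "C"])]
            pick = rng.choice(cand, size=min(-need, len(cand)), replace=False)
            arr[pick] = rng.choice(["A", "T"], size=len(pick))
    return AnnotatedGenome("ancestor", "".join(arr), features, circular=True)


# ------------------------------------------------------------- application


def _shift_features_insert(features: list[Feature], pos: int, k: int) -> list[Feature]:
    out = []
    for f in features:
        if f.start < pos < f.end:
            out.append(replace(f, end=f.end + k))
        elif f.start >= pos:
            out.append(replace(f, start=f.start + k, end=f.end + k))
        else:
            out.append(f)
    return out


def _shift_features_delete(features: list[Feature], pos: int, k: int) -> list[Feature]:
    out = []
    for f in features:
        if f.start >= pos + k:
            out.append(replace(f, start=f.start - k, end=f.end - k))
        elif f.start <= pos and f.end >= pos + k:
            if f.length - k >= 3:
                out.append(replace(f, end=f.end - k))
            # degenerate: feature reduced below a codon — drop it
        elif f.end <= pos:
            out.append(f)
        else:  # partial overlap — caller must prevent this
            raise ValueError("deletion crosses a feature boundary")
    return out


def apply_event(seq: list[str], features: list[Feature], ev) -> tuple[list, list]:
    """Apply one logged event; ``seq`` and ``features`` are updated in place."""
    if ev.etype == "sub":
        assert seq[ev.position] == ev.from_base, "replay mismatch"
        seq[ev.position] = ev.to_base
    elif ev.etype == "indel":
        if ev.kind == "ins":
            seq[ev.position : ev.position] = list(ev.seq)
            features[:] = _shift_features_insert(features, ev.position, ev.length)
        else:
            assert "".join(seq[ev.position : ev.position + ev.length]) == ev.seq
            del seq[ev.position : ev.position + ev.length]
            features[:] = _shift_features_delete(features, ev.position, ev.length)
    elif ev.etype == "inversion":
        a, b = ev.start, ev.end
        seq[a:b] = list(revcomp("".join(seq[a:b])))
        new = []
        for f in features:
            if f.start >= a and f.end <= b:
                new.append(
                    replace(
                        f,
                        start=a + (b - f.end),
                        end=a + (b - f.start),
                        strand=-f.strand,
                    )
                )
            elif f.end <= a or f.start >= b:
                new.append(f)
            else:
                raise ValueError("inversion crosses a feature boundary")
        new.sort(key=lambda f: f.start)
        features[:] = new
    elif ev.etype == "loss":
        if ev.mode == "pseudogenization":
            for p, frm, to in ev.spans:
                assert seq[p] == frm, "replay mismatch"
                seq[p] = to
            features[:] = [
                replace(f, kind="pseudogene") if f.family == ev.family else f
                for f in features
            ]
        else:  # deletion of full spans, applied high→low as logged
            for pos, dseq in ev.spans:
                k = len(dseq)
                assert "".join(seq[pos : pos + k]) == dseq
                del seq[pos : pos + k]
                # remove the deleted feature(s), shift the rest
                features[:] = [
                    f for f in features if not (f.start >= pos and f.end <= pos + k)
                ]
                features[:] = _shift_features_delete(features, pos, k)
    else:
        raise ValueError(f"unknown event type {ev.etype}")
    return seq, features


def replay(
    ancestor: AnnotatedGenome, log: TruthLog, tree: dendropy.Tree, leaf_label: str
) -> AnnotatedGenome:
    """Re-derive a leaf genome from the ancestor and the truth log."""
    node = next(
        (l for l in tree.leaf_node_iter() if l.taxon.label == leaf_label), None
    )
    if node is None:
        raise KeyError(leaf_label)
    path = []
    while node.parent_node is not None:
        path.append(_label(node))
        node = node.parent_node
    seq = list(ancestor.seq)
    features = list(ancestor.features)
    for branch in reversed(path):
        for ev in log.by_branch(branch):
            seq, features = apply_event(seq, features, ev)
    return AnnotatedGenome(leaf_label, "".join(seq), features, circular=True)


# --------------------------------------------------------------- evolution


def _label(node: dendropy.Node) -> str:
    if node.taxon is not None and node.taxon.label:
        return node.taxon.label
    return node.label or ""


def load_dated_tree(newick: str) -> dendropy.Tree:
    """Parse a rooted newick with branch lengths in My; label internals."""
    tree = dendropy.Tree.get(
        data=newick, schema="newick", suppress_internal_node_taxa=False
    )
    counter = [0]
    for nd in tree.preorder_node_iter():
        if not _label(nd):
            counter[0] += 1
            nd.label = f"N{counter[0]}"
    return tree


def node_ages(tree: dendropy.Tree) -> dict:
    """Ages (My before present) assuming an ultrametric tree, leaves at 0."""
    depth = {}
    for nd in tree.preorder_node_iter():
        d = 0.0 if nd.parent_node is None else depth[id(nd.parent_node)] + (
            nd.edge.length or 0.0
        )
        depth[id(nd)] = d
    root_age = max(depth[id(l)] for l in tree.leaf_node_iter())
    return {_label(nd): root_age - depth[id(nd)] for nd in tree.preorder_node_iter()}


def _run_lengths(arr: np.ndarray) -> np.ndarray:
    """Length of the mononucleotide run containing each position."""
    n = len(arr)
    if n == 0:
        return np.zeros(0, dtype=int)
    change = np.flatnonzero(arr[1:] != arr[:-1]) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [n]))
    lens = ends - starts
    return np.repeat(lens, lens)


def _coding_mask(features: Sequence[Feature], n: int) -> np.ndarray:
    mask = np.zeros(n, dtype=bool)
    for f in features:
        if f.kind != "pseudogene":
            mask[f.start : f.end] = True
    return mask


def _run_length_at(seq: list[str], pos: int) -> int:
    base = seq[pos]
    i = pos
    while i > 0 and seq[i - 1] == base:
        i -= 1
    j = pos
    n = len(seq)
    while j + 1 < n and seq[j + 1] == base:
        j += 1
    return j - i + 1


def _simulate_substitutions(
    seq, features, rng, params, t, branch, log
) -> None:
    q = params.directed_rates()
    bases = "ACGT"
    leave = {x: sum(q[(x, y)] for y in bases if y != x) for x in bases}
    lam_max = max(leave.values())
    if lam_max <= 0 or t <= 0:
        return
    n = len(seq)
    mask = _coding_mask(features, n)
    n_prop = rng.poisson(lam_max * t * n)
    for _ in range(n_prop):
        pos = int(rng.integers(n))
        x = seq[pos]
        if x not in leave:
            continue
        f = params.cds_sub_factor if mask[pos] else 1.0
        if rng.random() >= leave[x] * f / lam_max:
            continue
        ys = [y for y in bases if y != x]
        w = np.array([q[(x, y)] for y in ys])
        y = ys[rng.choice(3, p=w / w.sum())]
        ev = SubEvent("sub", branch, pos, x, y)
        apply_event(seq, features, ev)
        log.events.append(ev)


def _intergenic_positions(features, n):
    iv = []
    prev = 0
    for f in sorted(features, key=lambda f: f.start):
        if f.start > prev:
            iv.append((prev, f.start))
        prev = max(prev, f.end)
    if prev < n:
        iv.append((prev, n))
    return iv


def _sample_intergenic(rng, intervals):
    lens = np.array([b - a for a, b in intervals], dtype=float)
    i = rng.choice(len(intervals), p=lens / lens.sum())
    a, b = intervals[i]
    return int(rng.integers(a, b))


def _simulate_indels(seq, features, rng, params, t, branch, log) -> None:
    if params.indel_rate <= 0 or t <= 0:
        return
    arr = np.array(seq)
    runs = np.minimum(_run_lengths(arr), params.slippage_run_cap)
    w = params.indel_rate * params.slippage_multiplier ** (runs - 1.0)
    mask = _coding_mask(features, len(seq))
    w[mask] *= params.cds_indel_factor
    total = w.sum() * t
    n_ev = rng.poisson(total)
    if n_ev == 0:
        return
    p = w / w.sum()
    positions = sorted(rng.choice(len(seq), size=n_ev, p=p), reverse=True)
    for pos in positions:
        pos = int(min(pos, len(seq) - 1))
        ci = int(rng.choice(4, p=np.asarray(params.indel_class_weights)))
        lo, hi = INDEL_CLASSES[ci]
        length = int(rng.integers(lo, hi + 1))
        is_ins = rng.random() < params.insertion_prob[ci]
        region = "coding" if any(
            f.start <= pos < f.end and f.kind != "pseudogene" for f in features
        ) else "noncoding"
        if is_ins:
            if length == 1:
                ins = seq[pos]  # slippage-style duplication of the run base
            elif pos >= length:
                ins = "".join(seq[pos - length : pos])  # tandem duplication
            else:
                ins = _random_seq(rng, length, 0.4)
            ev = IndelEvent(
                "indel", branch, pos, length, "ins", ins,
                _run_length_at(seq, pos), region,
            )
        else:
            ok = False
            for _try in range(50):
                # a deletion may touch a feature only if the feature fully
                # contains it (in-gene indel); partial overlaps are resampled
                crosses = any(
                    f.end > pos
                    and f.start < pos + length
                    and not (f.start <= pos and f.end >= pos + length)
                    for f in features
                )
                if pos + length <= len(seq) and not crosses:
                    ok = True
                    break
                pos = int(min(rng.choice(len(p), p=p), len(seq) - 1))
            if not ok:
                continue
            dseq = "".join(seq[pos : pos + length])
            ev = IndelEvent(
                "indel", branch, pos, length, "del", dseq,
                _run_length_at(seq, pos), region,
            )
        apply_event(seq, features, ev)
        log.events.append(ev)


def _simulate_inversions(seq, features, rng, params, t, branch, log) -> None:
    if params.inversion_rate <= 0 or t <= 0:
        return
    n_ev = rng.poisson(params.inversion_rate * t)
    for _ in range(n_ev):
        placed = False
        for _try in range(100):
            by_family: dict[str, list[Feature]] = {}
            for f in features:
                by_family.setdefault(f.family, []).append(f)
            dups = [fs for fs in by_family.values() if len(fs) == 2]
            if dups and rng.random() < params.dup_breakpoint_prob:
                fs = sorted(dups[int(rng.integers(len(dups)))], key=lambda f: f.start)
                a, b = fs[0].end, fs[1].start
            else:
                iv = _intergenic_positions(features, len(seq))
                if len(iv) < 2:
                    break
                a = _sample_intergenic(rng, iv)
                b = _sample_intergenic(rng, iv)
                a, b = min(a, b), max(a, b)
            if b - a < 2:
                continue
            if any(f.start < a < f.end or f.start < b < f.end for f in features):
                continue
            ev = InversionEvent("inversion", branch, a, b)
            apply_event(seq, features, ev)
            log.events.append(ev)
            placed = True
            break
        if not placed:
            continue


def _loss_intensity(params, parent_age, child_age) -> float:
    lam = 0.0
    for a0, a1, r in params.gene_loss_rate_per_phase:
        lo = max(child_age, a1)
        hi = min(parent_age, a0)
        if hi > lo:
            lam += r * (hi - lo)
    return lam


def _pseudogenize_spans(seq, feat: Feature) -> list:
    """Substitutions converting a mid-gene codon to a premature stop."""
    n_codons = feat.length // 3
    ci = max(1, n_codons // 2)
    if feat.strand == 1:
        start = feat.start + 3 * ci
        target = "TAA"
    else:
        start = feat.end - 3 * ci - 3
        target = "TTA"  # revcomp of TAA on genome strand
    spans = []
    for k in range(3):
        frm = seq[start + k]
        to = target[k]
        if frm != to:
            spans.append((start + k, frm, to))
    return spans


def _simulate_losses(
    seq, features, rng, params, parent_age, child_age, branch, present, log
) -> None:
    lam = _loss_intensity(params, parent_age, child_age)
    if lam <= 0:
        return
    p_loss = 1.0 - np.exp(-lam)
    families = sorted(present)
    lost = [fam for fam in families if rng.random() < p_loss]
    for fam in lost:
        copies = [f for f in features if f.family == fam and f.kind != "pseudogene"]
        if not copies:
            present.discard(fam)
            continue
        if rng.random() < params.pseudogenization_prob:
            spans = []
            for f in copies:
                spans.extend(_pseudogenize_spans(seq, f))
            ev = LossEvent("loss", branch, fam, "pseudogenization", spans)
        else:
            spans = []
            for f in sorted(copies, key=lambda f: -f.start):
                spans.append((f.start, "".join(seq[f.start : f.end])))
            ev = LossEvent("loss", branch, fam, "deletion", spans)
        apply_event(seq, features, ev)
        log.events.append(ev)
        present.discard(fam)


def evolve_tree(
    ancestor: AnnotatedGenome, params: EvolutionParams
) -> tuple[dict, TruthLog]:
    """Evolve ``ancestor`` along ``params.tree``; return leaf genomes + log."""
    params.validate()
    tree = load_dated_tree(params.tree)
    ages = node_ages(tree)
    rng = np.random.default_rng(params.seed)
    log = TruthLog()
    leaves: dict[str, AnnotatedGenome] = {}

    root_families = sorted({f.family for f in ancestor.features})
    log.presence[_label(tree.seed_node)] = list(root_families)

    def descend(node, seq, features, present):
        for child in node.child_nodes():
            t = child.edge.length or 0.0
            branch = _label(child)
            cseq = list(seq)
            cfeat = list(features)
            cpresent = set(present)
            _simulate_substitutions(cseq, cfeat, rng, params, t, branch, log)
            _simulate_indels(cseq, cfeat, rng, params, t, branch, log)
            _simulate_inversions(cseq, cfeat, rng, params, t, branch, log)
            _simulate_losses(
                cseq, cfeat, rng, params,
                ages[_label(node)], ages[branch], branch, cpresent, log,
            )
            log.presence[branch] = sorted(cpresent)
            if child.is_leaf():
                leaves[branch] = AnnotatedGenome(
                    branch, "".join(cseq), cfeat, circular=True
                )
            else:
                descend(child, cseq, cfeat, cpresent)

    descend(
        tree.seed_node,
        list(ancestor.seq),
        list(ancestor.features),
        set(root_families),
    )
    return leaves, log
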