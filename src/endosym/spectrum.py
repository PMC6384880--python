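"""Outgroup polarization of variants and directional mutation-spectrum analysis.

Given a three-way alignment of two closely related ingroup genomes plus an
outgroup, differences between the ingroups are polarized by parsimony: the
allele shared with the outgroup is taken as ancestral and the change is
assigned to the other ingroup's branch. From the polarized set the module
computes the 12-class directional substitution spectrum, per-site relative
rates (counts divided by the frequency of the originating nucleotide),
normalized relative frequencies summing to 100%, the six collapsed
strand-complementary classes, the implied equilibrium GC content of the
two-state GC↔AT per-site process, a chi-square test for directional bias,
insertion/deletion direction tallies, and the association of indels with
ancestral mononucleotide runs (homopolymers).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .align import GAP, MultiAlignment
from .genome import Feature

BASES = "ACGT"
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}
DIRECTED = [f"{x}>{y}" for x in BASES for y in BASES if x != y]
# collapsed classes keyed by their purine-from / A-from representative
COLLAPSED = ("A>G", "A>C", "A>T", "G>A", "G>T", "G>C")


def collapse_class(change: str) -> str:
    x, y = change.split(">")
    if f"{x}>{y}" in COLLAPSED:
        return f"{x}>{y}"
    return f"{_COMP[x]}>{_COMP[y]}"


@dataclass
class PolarizedVariant:
    position: int  # on outgroup (ancestral) coordinates
    ancestral: str
    derived: str
    lineage: str  # ingroup branch bearing the derived state
    kind: str  # "SNP" | "ins" | "del"
    length: int = 1
    region: str = "noncoding"


@dataclass
class PolarizedVariantSet:
    variants: list = field(default_factory=list)
    n_unpolarizable: int = 0  # outgroup matches neither ingroup
    n_shared: int = 0  # both ingroups differ identically from the outgroup
    n_outgroup_gap: int = 0

    @property
    def snps(self) -> list:
        return [v for v in self.variants if v.kind == "SNP"]

    @property
    def indels(self) -> list:
        return [v for v in self.variants if v.kind in ("ins", "del")]


def _region_of(pos: int, length: int, features) -> str:
    span = max(length, 1)
    cov = 0
    for f in features:
        if f.kind == "pseudogene":
            continue
        cov += max(0, min(pos + span, f.end) - max(pos, f.start))
    return "coding" if cov * 2 > span else "noncoding"


def polarize(
    threeway: MultiAlignment,
    ingroups: tuple,
    outgroup: str,
    annotations: tuple = (),
) -> PolarizedVariantSet:
    """Assign ancestral/derived states to ingroup differences by parsimony.

    Only differences *between the two ingroups* are polarized; sites where
    both ingroups share a state that differs from the outgroup are counted
    as ``n_shared`` (changes on the stem or outgroup branch), and sites
    where the outgroup matches neither ingroup as ``n_unpolarizable``.
    Indels are polarized only when the outgroup agrees exactly with one
    ingroup across the whole event span.
    """
    in1, in2 = ingroups
    rows = {k: threeway.rows[k] for k in (outgroup, in1, in2)}
    arr = {k: np.frombuffer(v.encode(), dtype="S1") for k, v in rows.items()}
    gap = {k: arr[k] == b"-" for k in arr}
    outpos = threeway.col_to_pos(outgroup)
    pv = PolarizedVariantSet()

    # --- SNP columns (gapless)
    gapless = ~(gap[outgroup] | gap[in1] | gap[in2])
    diff12 = arr[in1] != arr[in2]
    for c in np.flatnonzero(gapless & diff12):
        o, a1, a2 = (arr[k][c].decode() for k in (outgroup, in1, in2))
        pos = int(outpos[c])
        region = _region_of(pos, 1, annotations)
        if o == a1:
            pv.variants.append(PolarizedVariant(pos, o, a2, in2, "SNP", 1, region))
        elif o == a2:
            pv.variants.append(PolarizedVariant(pos, o, a1, in1, "SNP", 1, region))
        else:
            pv.n_unpolarizable += 1
    # shared SNPs: both ingroups equal but differ from outgroup
    shared = gapless & ~diff12 & (arr[in1] != arr[outgroup])
    pv.n_shared += int(shared.sum())

    # --- indel runs: maximal runs of a constant non-trivial gap pattern
    pat = (
        gap[outgroup].astype(int) * 4 + gap[in1].astype(int) * 2 + gap[in2].astype(int)
    )
    n = len(pat)
    c = 0
    while c < n:
        p = pat[c]
        e = c
        while e < n and pat[e] == p:
            e += 1
        if p != 0:
            length = e - c
            pos = int(outpos[c])
            seqs = {k: rows[k][c:e] for k in rows}
            region = _region_of(pos, length, annotations)
            if p == 2 or p == 1:  # gap in exactly one ingroup
                gapped, other = (in1, in2) if p == 2 else (in2, in1)
                if seqs[outgroup] == seqs[other]:
                    pv.variants.append(
                        PolarizedVariant(
                            pos, seqs[outgroup], "-" * length, gapped, "del",
                            length, region,
                        )
                    )
                else:
                    pv.n_unpolarizable += 1
            elif p in (6, 5):  # outgroup gap + one ingroup gap: insertion
                bearer = in2 if p == 6 else in1
                pv.variants.append(
                    PolarizedVariant(
                        pos, "-" * length, seqs[bearer], bearer, "ins", length, region
                    )
                )
            elif p == 4:  # outgroup gap only: both ingroups carry sequence
                if seqs[in1] == seqs[in2]:
                    pv.n_shared += 1  # shared insertion on the stem
                else:
                    pv.n_outgroup_gap += 1
            elif p == 3:  # both ingroups gap, outgroup has sequence: stem deletion
                pv.n_shared += 1
            elif p == 7:
                pass  # all-gap columns cannot occur in a valid alignment
        c = e
    return pv


# ------------------------------------------------------------- the spectrum


@dataclass
class SpectrumTable:
    """Directional substitution counts, per-site rates, and collapsed classes."""

    counts: dict  # 12 directed classes
    ancestral_base_counts: dict  # base -> count in ancestral sequence
    per_site_rates: dict  # 12 classes, count / freq(origin base)
    normalized_pct: dict  # 12 classes, rates rescaled to sum 100
    collapsed_counts: dict  # 6 classes
    collapsed_rates: dict  # pooled counts / pooled origin-base counts
    collapsed_pct: dict  # 6 classes, sums to 100
    n_transitions: int = 0
    n_transversions: int = 0

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for cls in DIRECTED:
            rows.append(
                {
                    "class": cls,
                    "count": self.counts[cls],
                    "per_site_rate": self.per_site_rates[cls],
                    "normalized_pct": self.normalized_pct[cls],
                }
            )
        return pd.DataFrame(rows)

    def collapsed_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "class": list(COLLAPSED),
                "count": [self.collapsed_counts[c] for c in COLLAPSED],
                "per_site_rate": [self.collapsed_rates[c] for c in COLLAPSED],
                "normalized_pct": [self.collapsed_pct[c] for c in COLLAPSED],
            }
        )


TRANSITIONS = {"A>G", "G>A", "C>T", "T>C"}


def spectrum(pv: PolarizedVariantSet, ancestral_seq: str) -> SpectrumTable:
    """Directional spectrum with per-site normalization and collapsing.

    Per-site relative rate of class X→Y is count(X→Y) divided by the number
    of X sites in the ancestral sequence; normalized percentages rescale the
    12 rates to sum to 100%, and complementary-strand classes are pooled
    into six collapsed classes (pooled counts over pooled origin bases).
    """
    base_counts = {b: ancestral_seq.count(b) for b in BASES}
    counts = {cls: 0 for cls in DIRECTED}
    for v in pv.snps:
        if v.ancestral in BASES and v.derived in BASES:
            counts[f"{v.ancestral}>{v.derived}"] += 1
    rates = {}
    for cls in DIRECTED:
        x = cls[0]
        if base_counts[x] == 0:
            if counts[cls] > 0:
                raise ValueError(
                    f"observed {cls} changes but no ancestral {x} sites"
                )
            rates[cls] = 0.0
        else:
            rates[cls] = counts[cls] / base_counts[x]
    total_rate = sum(rates.values())
    if total_rate == 0:
        norm = {cls: 0.0 for cls in DIRECTED}
    else:
        norm = {cls: 100.0 * r / total_rate for cls, r in rates.items()}

    coll_counts = {c: 0 for c in COLLAPSED}
    for cls in DIRECTED:
        coll_counts[collapse_class(cls)] += counts[cls]
    coll_rates = {}
    for c in COLLAPSED:
        x = c[0]
        pooled_sites = base_counts[x] + base_counts[_COMP[x]]
        if pooled_sites == 0:
            if coll_counts[c] > 0:
                raise ValueError(f"observed {c} changes but no source sites")
            coll_rates[c] = 0.0
        else:
            coll_rates[c] = coll_counts[c] / pooled_sites
    coll_total = sum(coll_rates.values())
    if coll_total == 0:
        coll_pct = {c: 0.0 for c in COLLAPSED}
    else:
        coll_pct = {c: 100.0 * r / coll_total for c, r in coll_rates.items()}

    return SpectrumTable(
        counts=counts,
        ancestral_base_counts=base_counts,
        per_site_rates=rates,
        normalized_pct=norm,
        collapsed_counts=coll_counts,
        collapsed_rates=coll_rates,
        collapsed_pct=coll_pct,
        n_transitions=sum(counts[c] for c in DIRECTED if c in TRANSITIONS),
        n_transversions=sum(counts[c] for c in DIRECTED if c not in TRANSITIONS),
    )


def equilibrium_gc(spec: SpectrumTable) -> float:
    """Stationary GC percentage of the two-state GC↔AT per-site process.

    With per-site rates u(GC→AT) and u(AT→GC), the equilibrium GC fraction
    is u(AT→GC) / (u(AT→GC) + u(GC→AT)); returned as a percentage.
    Scale-invariant: multiplying all rates by a constant leaves it unchanged.
    """
    u_gc2at = spec.collapsed_rates["G>A"] + spec.collapsed_rates["G>T"]
    u_at2gc = spec.collapsed_rates["A>G"] + spec.collapsed_rates["A>C"]
    if u_gc2at + u_at2gc == 0:
        raise ValueError("both directional rates are zero; equilibrium undefined")
    return 100.0 * u_at2gc / (u_at2gc + u_gc2at)


def directional_chi_square(
    spec: SpectrumTable, expectation: str = "per_site"
) -> tuple:
    """1-df chi-square of GC→AT vs AT→GC counts.

    ``expectation="per_site"`` (default) sets expected counts proportional
    to ancestral GC vs AT site counts (a test of equal per-site rates);
    ``expectation="equal"`` uses a 50/50 split.
    """
    n_gc2at = spec.collapsed_counts["G>A"] + spec.collapsed_counts["G>T"]
    n_at2gc = spec.collapsed_counts["A>G"] + spec.collapsed_counts["A>C"]
    total = n_gc2at + n_at2gc
    if total == 0:
        raise ValueError("no directional changes observed")
    if expectation == "per_site":
        bc = spec.ancestral_base_counts
        n_gc = bc["G"] + bc["C"]
        n_at = bc["A"] + bc["T"]
        if n_gc + n_at == 0:
            raise ValueError("empty ancestral sequence")
        exp = np.array([n_gc, n_at], dtype=float) / (n_gc + n_at) * total
    elif expectation == "equal":
        exp = np.array([total / 2, total / 2])
    else:
        raise ValueError(f"unknown expectation {expectation!r}")
    stat, p = stats.chisquare([n_gc2at, n_at2gc], f_exp=exp)
    return float(stat), float(p)


# ---------------------------------------------------- indels & homopolymers


def homopolymer_runs(seq: str) -> pd.Series:
    """Count of mononucleotide runs per run length in ``seq``."""
    arr = np.frombuffer(seq.encode(), dtype="S1")
    if len(arr) == 0:
        return pd.Series(dtype=int)
    change = np.flatnonzero(arr[1:] != arr[:-1]) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [len(arr)]))
    lens = ends - starts
    return pd.Series(lens).value_counts().sort_index()


def _run_length_at(seq: str, pos: int) -> int:
    if not 0 <= pos < len(seq):
        return 0
    b = seq[pos]
    i = pos
    while i > 0 and seq[i - 1] == b:
        i -= 1
    j = pos
    while j + 1 < len(seq) and seq[j + 1] == b:
        j += 1
    return j - i + 1


def indel_direction_and_homopolymers(
    pv: PolarizedVariantSet, ancestral_seq: str
) -> tuple:
    """Insertion/deletion tallies, net length change, and homopolymer table.

    Direction is relative to the ancestral (outgroup) state: net bp equals
    inserted minus deleted bases. Each indel is assigned to one ancestral
    mononucleotide-run row: deletions to the run containing the first
    deleted base; insertions to the longer of the runs containing or
    abutting the insertion point (run length 1 means "not in a run").
    """
    ins = [v for v in pv.indels if v.kind == "ins"]
    dels = [v for v in pv.indels if v.kind == "del"]
    net = sum(v.length for v in ins) - sum(v.length for v in dels)

    run_counts = homopolymer_runs(ancestral_seq)
    events: dict[int, int] = {}
    for v in pv.indels:
        if v.kind == "del":
            r = _run_length_at(ancestral_seq, v.position)
        else:
            r = max(
                _run_length_at(ancestral_seq, v.position),
                _run_length_at(ancestral_seq, v.position - 1),
            )
        r = max(r, 1)
        events[r] = events.get(r, 0) + 1

    idx = sorted(set(run_counts.index) | set(events))
    table = pd.DataFrame(
        {
            "run_length": idx,
            "n_runs": [int(run_counts.get(i, 0)) for i in idx],
            "indel_events": [events.get(i, 0) for i in idx],
        }
    )
    table["events_per_run"] = table["indel_events"] / table["n_runs"].replace(0, np.nan)
    return len(ins), len(dels), net, table
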