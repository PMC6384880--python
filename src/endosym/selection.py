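"""NG86 dN/dS, codon adaptation index, and gene-group comparisons.

dN/dS follows the Nei–Gojobori (1986) counting method: synonymous and
nonsynonymous *sites* per codon are the expected fractions of the three
possible changes at each position that preserve the amino acid (changes to
stop codons excluded from both numerator and denominator); *differences*
between codons differing at 2–3 positions are averaged over all mutational
pathways with equal weight, skipping pathways that pass through a stop
codon. Proportions are Jukes–Cantor corrected: d = −(3/4)·ln(1 − 4p/3).
Pairs with dS outside a configurable window (default (0.01, 2]) are flagged
as filtered — very low dS means insufficient divergence, very high dS means
saturation.

CAI follows the Sharp–Li convention: the geometric mean of per-codon
relative adaptiveness w (frequency over the maximum frequency within the
synonymous family, from a reference usage table), excluding single-codon
families (Met, Trp) and stops; zero-w codons are floored.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

GENETIC_CODE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}
BASES = "ACGT"


class CodonAlignmentError(ValueError):
    pass


def codons(seq: str) -> list:
    if len(seq) % 3:
        raise CodonAlignmentError("length not divisible by 3")
    return [seq[i : i + 3] for i in range(0, len(seq), 3)]


def validate_codon_alignment(*seqs: str) -> None:
    lens = {len(s) for s in seqs}
    if len(lens) > 1:
        raise CodonAlignmentError("sequences differ in length")
    for s in seqs:
        cs = codons(s)
        for i, c in enumerate(cs[:-1]):
            if GENETIC_CODE.get(c) == "*":
                raise CodonAlignmentError(f"internal stop codon at codon {i}")


# ------------------------------------------------------------------- NG86


def _syn_nonsyn_sites(codon: str) -> tuple:
    """Expected synonymous / nonsynonymous sites of one codon (NG86).

    At each position, the synonymous fraction is the share of the non-stop
    single-base changes that preserve the amino acid; each position
    contributes one site split between the two categories.
    """
    aa = GENETIC_CODE[codon]
    s = 0.0
    for i in range(3):
        syn = 0
        valid = 0
        for b in BASES:
            if b == codon[i]:
                continue
            alt = codon[:i] + b + codon[i + 1 :]
            if GENETIC_CODE[alt] == "*":
                continue
            valid += 1
            if GENETIC_CODE[alt] == aa:
                syn += 1
        s += syn / valid if valid else 0.0
    return s, 3.0 - s


def _pathway_differences(c1: str, c2: str) -> tuple:
    """Average synonymous/nonsynonymous difference counts over all equally
    weighted mutational pathways between two codons, skipping pathways that
    pass through a stop codon."""
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    syn_tot = nsyn_tot = 0.0
    n_paths = 0
    for perm in itertools.permutations(diff):
        cur = c1
        syn = nsyn = 0
        ok = True
        for i in perm:
            nxt = cur[:i] + c2[i] + cur[i + 1 :]
            if GENETIC_CODE[nxt] == "*":
                ok = False
                break
            if GENETIC_CODE[nxt] == GENETIC_CODE[cur]:
                syn += 1
            else:
                nsyn += 1
            cur = nxt
        if ok:
            syn_tot += syn
            nsyn_tot += nsyn
            n_paths += 1
    if n_paths == 0:
        # all pathways blocked by stops: fall back to equal weighting over
        # every pathway, counting the stop-passing steps as nonsynonymous
        for perm in itertools.permutations(diff):
            cur = c1
            for i in perm:
                nxt = cur[:i] + c2[i] + cur[i + 1 :]
                if GENETIC_CODE[nxt] == GENETIC_CODE[cur]:
                    syn_tot += 1
                else:
                    nsyn_tot += 1
                cur = nxt
            n_paths += 1
    return syn_tot / n_paths, nsyn_tot / n_paths


def jukes_cantor(p: float) -> float:
    """JC69 multiple-hit correction; undefined for p ≥ 3/4."""
    if p >= 0.75:
        raise ValueError("proportion ≥ 0.75: correction undefined")
    if p == 0:
        return 0.0
    return -0.75 * math.log(1 - 4 * p / 3)


@dataclass
class DnDsRecord:
    gene: str
    pair: str
    dn: float | None
    ds: float | None
    ratio: float | None
    filtered: bool = False
    reason: str = ""


def ng86_dnds(
    seq1: str,
    seq2: str,
    gene: str = "",
    pair: str = "",
    ds_window: tuple = (0.01, 2.0),
) -> DnDsRecord:
    """Pairwise dN/dS by the NG86 counting method.

    ``ds_window=(lo, hi)``: the ratio is reported only when lo < dS ≤ hi;
    otherwise the record is flagged (insufficient divergence / saturation).
    Records are symmetric in the two sequences; self-concatenation leaves
    dN and dS unchanged.
    """
    validate_codon_alignment(seq1, seq2)
    cs1, cs2 = codons(seq1), codons(seq2)
    if not cs1:
        raise CodonAlignmentError("zero-length alignment")
    S = N = Sd = Nd = 0.0
    for c1, c2 in zip(cs1, cs2):
        if "*" in (GENETIC_CODE[c1], GENETIC_CODE[c2]):
            continue  # terminal stops carry no sites
        s1, n1 = _syn_nonsyn_sites(c1)
        s2, n2 = _syn_nonsyn_sites(c2)
        S += (s1 + s2) / 2
        N += (n1 + n2) / 2
        sd, nd = _pathway_differences(c1, c2)
        Sd += sd
        Nd += nd
    if S == 0 or N == 0:
        raise CodonAlignmentError("no countable sites")
    ps, pn = Sd / S, Nd / N
    try:
        ds = jukes_cantor(ps)
        dn = jukes_cantor(pn)
    except ValueError:
        return DnDsRecord(gene, pair, None, None, None, True, "jc_undefined")
    lo, hi = ds_window
    if ds <= lo or ds > hi:
        reason = "ds_too_low" if ds <= lo else "ds_saturated"
        return DnDsRecord(gene, pair, dn, ds, None, True, reason)
    return DnDsRecord(gene, pair, dn, ds, dn / ds, False, "")


def group_dnds_summary(records: list, groups: dict) -> dict:
    """Per-group mean dN/dS (gene-averaged over pairs) and Welch t-tests.

    ``groups`` maps gene id → group label (a partition). Per gene, unfiltered
    pairwise ratios are averaged first; group means are over gene averages.
    Adjacent groups (sorted by label) are compared by Welch's two-sample
    t-test (Student's available via ``equal_var`` in scipy directly).
    """
    per_gene: dict[str, list] = {}
    n_filtered = 0
    for r in records:
        if r.filtered or r.ratio is None:
            n_filtered += 1
            continue
        per_gene.setdefault(r.gene, []).append(r.ratio)
    # sorted aggregation keeps results exactly invariant to record order
    gene_means = {g: float(np.mean(sorted(v))) for g, v in per_gene.items()}
    by_group: dict[str, list] = {}
    for g in sorted(gene_means):
        grp = groups.get(g)
        if grp is not None:
            by_group.setdefault(grp, []).append(gene_means[g])
    labels = sorted(by_group)
    for lab in labels:
        if len(by_group[lab]) < 2:
            raise ValueError(f"group {lab} has fewer than 2 usable genes")
    summary = {
        "group_means": {lab: float(np.mean(by_group[lab])) for lab in labels},
        "group_n": {lab: len(by_group[lab]) for lab in labels},
        "n_filtered_records": n_filtered,
        "n_retained_records": sum(len(v) for v in per_gene.values()),
        "tests": {},
    }
    for a, b in zip(labels, labels[1:]):
        x, y = by_group[a], by_group[b]
        if len(set(x)) == 1 and len(set(y)) == 1:
            t, p = (0.0, 1.0) if np.mean(x) == np.mean(y) else (float("inf"), 0.0)
            flag = "zero_variance"
        else:
            t, p = stats.ttest_ind(x, y, equal_var=False)
            flag = ""
        summary["tests"][f"{a}_vs_{b}"] = {
            "t": float(t),
            "p": float(p),
            "flag": flag,
        }
    return summary


# -------------------------------------------------------------------- CAI


@dataclass
class CodonUsageTable:
    """Relative adaptiveness w per codon from reference usage counts."""

    w: dict = field(default_factory=dict)

    @classmethod
    def from_counts(cls, counts: dict) -> "CodonUsageTable":
        fams: dict[str, list] = {}
        for codon, aa in GENETIC_CODE.items():
            if aa != "*":
                fams.setdefault(aa, []).append(codon)
        w = {}
        for aa, cods in fams.items():
            mx = max(counts.get(c, 0) for c in cods)
            for c in cods:
                w[c] = counts.get(c, 0) / mx if mx > 0 else 0.0
        return cls(w)

    @classmethod
    def from_tsv(cls, path) -> "CodonUsageTable":
        df = pd.read_csv(path, sep="\t")
        col = "count" if "count" in df.columns else "frequency"
        counts = dict(zip(df["codon"].str.upper(), df[col].astype(float)))
        return cls.from_counts(counts)

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            {"codon": list(self.w), "w": list(self.w.values())}
        ).to_csv(path, sep="\t", index=False)


SINGLE_CODON_AAS = {"M", "W"}


def cai(cds: str, usage: CodonUsageTable, w_floor: float = 0.01) -> float:
    """Codon adaptation index: geometric mean of relative adaptiveness.

    Met and Trp codons (single-codon families) and stop codons are excluded
    per the Sharp–Li convention; codons with w = 0 in the reference table
    are floored at ``w_floor`` (flagging in the caller's hands).
    """
    logs = []
    for c in codons(cds.upper()):
        aa = GENETIC_CODE.get(c)
        if aa is None or aa == "*" or aa in SINGLE_CODON_AAS:
            continue
        w = usage.w.get(c, 0.0)
        if w <= 0:
            w = w_floor
        logs.append(math.log(w))
    if not logs:
        raise ValueError("no countable codons for CAI")
    return math.exp(sum(logs) / len(logs))
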