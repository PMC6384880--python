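"""Anchor-and-chain alignment of near-identical collinear genomes.

The aligner targets genomes a few percent diverged that share gene order
(collinear after rotating the circular sequences to a common gene): unique
exact k-mer matches are chained colinearly, and the short inter-anchor
segments are closed by banded global alignment with affine gap penalties.
Pairwise alignments sharing an outgroup genome can be projected onto the
outgroup coordinate system to produce a three-way alignment, from which SNPs
and indels are called with coding/noncoding region labels.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .genome import AnnotatedGenome, Feature

GAP = "-"

# Affine scoring for the gap-closure step (match, mismatch, open, extend).
MATCH = 2
MISMATCH = -3
GAP_OPEN = -5
GAP_EXTEND = -2
_NEG = -(10**9)


class AlignmentError(ValueError):
    pass


@dataclass
class MultiAlignment:
    """Gapped rows keyed by genome id, with column↔position coordinate maps."""

    rows: dict[str, str]

    def __post_init__(self) -> None:
        lens = {len(s) for s in self.rows.values()}
        if len(lens) > 1:
            raise AlignmentError("rows have unequal gapped length")

    @property
    def ncols(self) -> int:
        return len(next(iter(self.rows.values())))

    def ungapped(self, row: str) -> str:
        return self.rows[row].replace(GAP, "")

    def col_to_pos(self, row: str) -> np.ndarray:
        """For each column, the sequence position (non-gap count before it);
        gap columns carry the position of the next non-gap base."""
        arr = np.frombuffer(self.rows[row].encode(), dtype="S1")
        nongap = arr != b"-"
        return np.cumsum(nongap) - nongap.astype(int)

    def pos_to_col(self, row: str) -> np.ndarray:
        arr = np.frombuffer(self.rows[row].encode(), dtype="S1")
        return np.flatnonzero(arr != b"-")

    def column(self, i: int) -> dict:
        return {k: v[i] for k, v in self.rows.items()}

    def write_maf(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("##maf version=1\n\na\n")
            for rid, row in self.rows.items():
                n = len(row.replace(GAP, ""))
                fh.write(f"s {rid} 0 {n} + {n} {row}\n")


@dataclass
class VariantCall:
    kind: str  # "SNP" | "insertion" | "deletion"
    col_start: int
    col_end: int  # exclusive
    alleles: dict  # row id -> allele string ("-" for gap)
    region: str  # "coding" | "noncoding"
    length: int
    ref_pos: int  # 0-based position on the reference row
    genome: str = ""  # for indels: the genome bearing the gap/extra sequence


# ------------------------------------------------------------------ anchors


def find_anchors(a: str, b: str, k: int = 21, stride_target: int = 250_000):
    """Unique exact k-mer matches between ``a`` and ``b``.

    For large genomes, k-mers are subsampled by hash so the anchor list stays
    near ``stride_target`` entries; chaining only needs a sparse scaffold.
    """
    def unique_kmers(s: str) -> dict:
        seen: dict[str, int] = {}
        dup = set()
        mod = max(1, len(s) // stride_target)
        for i in range(len(s) - k + 1):
            km = s[i : i + k]
            if mod > 1 and hash(km) % mod:
                continue
            if km in dup:
                continue
            if km in seen:
                del seen[km]
                dup.add(km)
            else:
                seen[km] = i
        return seen

    ka = unique_kmers(a)
    kb = unique_kmers(b)
    anchors = sorted((pa, kb[km]) for km, pa in ka.items() if km in kb)
    return anchors


def chain_anchors(anchors: Sequence[tuple], k: int) -> list:
    """Longest strictly-increasing (in both genomes) non-overlapping chain."""
    if not anchors:
        return []
    # LIS on the b-coordinate (anchors already sorted by a).
    bs = [b for _, b in anchors]
    tails: list[int] = []
    tails_idx: list[int] = []
    prev = [-1] * len(bs)
    for i, x in enumerate(bs):
        j = bisect.bisect_left(tails, x)
        if j == len(tails):
            tails.append(x)
            tails_idx.append(i)
        else:
            tails[j] = x
            tails_idx[j] = i
        prev[i] = tails_idx[j - 1] if j > 0 else -1
    chain = []
    i = tails_idx[-1]
    while i >= 0:
        chain.append(anchors[i])
        i = prev[i]
    chain.reverse()
    # enforce non-overlap in both genomes
    out = []
    la = lb = -(10**9)
    for pa, pb in chain:
        if pa >= la + k and pb >= lb + k:
            out.append((pa, pb))
            la, lb = pa, pb
    return out


# ------------------------------------------------- banded affine alignment


def banded_affine(a: str, b: str, band: int, max_band: int = 4096):
    """Global alignment of two (short) segments, banded around the diagonal.

    Returns gapped strings (ga, gb). The band doubles automatically whenever
    the optimal path touches the band edge, up to ``max_band`` (or the full
    matrix for short segments); beyond that an :class:`AlignmentError` is
    raised — typically a sign the inputs are not collinear.
    """
    if not a and not b:
        return "", ""
    if not a:
        return GAP * len(b), b
    if not b:
        return a, GAP * len(a)
    n, m = len(a), len(b)
    band = max(band, abs(n - m) + 2)
    full = max(n, m)
    while True:
        if (n + 1) * (2 * band + 1) > 30_000_000:
            raise AlignmentError(
                f"band overflow aligning segments of length {n} and {m}"
            )
        ga, gb, touched = _banded_core(a, b, band)
        if not touched or band >= full:
            return ga, gb
        band *= 2
        if band > max_band and band < full:
            raise AlignmentError(
                f"band overflow aligning segments of length {n} and {m}"
            )


_INF = np.int64(10**15)


def _banded_core(a: str, b: str, band: int):
    """Vectorized banded affine DP (states M, X=gap-in-b, Y=gap-in-a)."""
    n, m = len(a), len(b)
    B = band
    W = 2 * B + 1
    oe = GAP_OPEN + GAP_EXTEND
    aa = np.frombuffer(a.encode(), dtype=np.uint8)
    bb = np.frombuffer(b.encode(), dtype=np.uint8)
    ks = np.arange(W)
    M = np.full((n + 1, W), -_INF, dtype=np.int64)
    X = np.full((n + 1, W), -_INF, dtype=np.int64)
    Y = np.full((n + 1, W), -_INF, dtype=np.int64)
    # row 0: j = k - B
    M[0, B] = 0
    j0 = ks - B
    valid0 = (j0 >= 1) & (j0 <= m)
    Y[0, valid0] = GAP_OPEN + GAP_EXTEND * j0[valid0]
    for i in range(1, n + 1):
        j = i + ks - B  # column per band offset
        valid = (j >= 0) & (j <= m)
        # M: diagonal from row i-1, same k
        jd = j >= 1
        sub = np.where(
            jd & valid,
            np.where(aa[i - 1] == bb[np.clip(j - 1, 0, m - 1)], MATCH, MISMATCH),
            -_INF,
        )
        prev_best = np.maximum(np.maximum(M[i - 1], X[i - 1]), Y[i - 1])
        Mrow = np.where(jd & valid, prev_best + sub, -_INF)
        # X: vertical from row i-1, band offset k+1
        shift = lambda arr: np.concatenate((arr[1:], [-_INF]))
        Xrow = np.maximum(
            np.maximum(shift(M[i - 1]) + oe, shift(X[i - 1]) + GAP_EXTEND),
            shift(Y[i - 1]) + oe,
        )
        Xrow = np.where(valid, Xrow, -_INF)
        # Y: horizontal within the row — running max over band offsets
        c = np.maximum(Mrow, Xrow) + GAP_OPEN
        e = np.maximum.accumulate(c - GAP_EXTEND * ks)
        d = e + GAP_EXTEND * ks  # d[k] = max(c[k], d[k-1]+ext)
        Yrow = np.full(W, -_INF, dtype=np.int64)
        Yrow[1:] = d[:-1] + GAP_EXTEND
        Yrow = np.where(valid & (j >= 1), Yrow, -_INF)
        np.clip(Mrow, -_INF, None, out=Mrow)
        M[i], X[i], Y[i] = Mrow, Xrow, Yrow
    k_end = m - n + B
    if not 0 <= k_end < W:
        return "", "", True  # target outside band: must widen
    finals = [M[n, k_end], X[n, k_end], Y[n, k_end]]
    st = int(np.argmax(finals))
    if finals[st] <= -_INF // 2:
        return "", "", True
    ga, gb = [], []
    i, k = n, k_end
    touched = False
    while True:
        j = i + k - B
        if i == 0 and j == 0:
            break
        if k == 0 or k == W - 1:
            touched = True
        if st == 0:  # M: came diagonally
            sub = MATCH if a[i - 1] == b[j - 1] else MISMATCH
            ga.append(a[i - 1])
            gb.append(b[j - 1])
            target = M[i, k] - sub
            i -= 1
            for ps, arr in ((0, M), (1, X), (2, Y)):
                if arr[i, k] == target:
                    st = ps
                    break
            if i == 0 and k == B:
                st = 0
        elif st == 1:  # X: consumed a[i-1], gap in b
            ga.append(a[i - 1])
            gb.append(GAP)
            v = X[i, k]
            i -= 1
            k += 1
            if X[i, k] + GAP_EXTEND == v:
                st = 1
            elif M[i, k] + oe == v:
                st = 0
            else:
                st = 2
        else:  # Y: consumed b[j-1], gap in a
            ga.append(GAP)
            gb.append(b[j - 1])
            v = Y[i, k]
            k -= 1
            if Y[i, k] + GAP_EXTEND == v:
                st = 2
            elif M[i, k] + oe == v:
                st = 0
            else:
                st = 1
    return "".join(reversed(ga)), "".join(reversed(gb)), touched


# ----------------------------------------------------------- pairwise path


def align_pair(
    genome_a: AnnotatedGenome | str,
    genome_b: AnnotatedGenome | str,
    k: int = 21,
    band: int = 16,
    ids: tuple = ("A", "B"),
) -> MultiAlignment:
    """Align two collinear genomes; returns a 2-row :class:`MultiAlignment`.

    Caller is responsible for rotating circular genomes to a shared start
    (see :meth:`AnnotatedGenome.rotate_to_gene`).
    """
    a = genome_a.seq if isinstance(genome_a, AnnotatedGenome) else genome_a
    b = genome_b.seq if isinstance(genome_b, AnnotatedGenome) else genome_b
    ida = genome_a.id if isinstance(genome_a, AnnotatedGenome) else ids[0]
    idb = genome_b.id if isinstance(genome_b, AnnotatedGenome) else ids[1]
    if a == b:
        return MultiAlignment({ida: a, idb: b})
    anchors = chain_anchors(find_anchors(a, b, k=k), k)
    if not anchors:
        if max(len(a), len(b)) > 50_000:
            raise AlignmentError(
                "no unique anchors found; try a smaller seed length k"
            )
        ga, gb = banded_affine(a, b, band=max(band, abs(len(a) - len(b)) + 2))
        return MultiAlignment({ida: ga, idb: gb})
    parts_a: list[str] = []
    parts_b: list[str] = []
    pa = pb = 0
    for qa, qb in anchors:
        ga, gb = banded_affine(a[pa:qa], b[pb:qb], band)
        parts_a.append(ga)
        parts_b.append(gb)
        parts_a.append(a[qa : qa + k])
        parts_b.append(b[qb : qb + k])
        pa, pb = qa + k, qb + k
    ga, gb = banded_affine(a[pa:], b[pb:], band)
    parts_a.append(ga)
    parts_b.append(gb)
    return MultiAlignment({ida: "".join(parts_a), idb: "".join(parts_b)})


def project_threeway(
    aln1: MultiAlignment, aln2: MultiAlignment, outgroup: str
) -> MultiAlignment:
    """Merge two pairwise alignments sharing ``outgroup`` onto its coordinates.

    Output columns: for every outgroup base one matched column; outgroup-gap
    (insertion) columns from either input are interleaved before the base
    they precede, with the absent ingroup shown as gap.
    """
    if outgroup not in aln1.rows or outgroup not in aln2.rows:
        raise AlignmentError("both alignments must contain the outgroup row")
    if aln1.ungapped(outgroup) != aln2.ungapped(outgroup):
        raise AlignmentError("outgroup sequences differ between alignments")
    (in1,) = [r for r in aln1.rows if r != outgroup]
    (in2,) = [r for r in aln2.rows if r != outgroup]
    out_seq = aln1.ungapped(outgroup)
    n = len(out_seq)

    def split_insertions(aln, ingroup):
        """Per outgroup position: ingroup chars inserted before it, and the
        ingroup char aligned to it."""
        before = [""] * (n + 1)
        at = [""] * n
        p = 0
        orow, irow = aln.rows[outgroup], aln.rows[ingroup]
        for oc, ic in zip(orow, irow):
            if oc == GAP:
                before[p] += ic
            else:
                at[p] = ic
                p += 1
        return before, at

    b1, a1 = split_insertions(aln1, in1)
    b2, a2 = split_insertions(aln2, in2)
    rows = {outgroup: [], in1: [], in2: []}
    for p in range(n + 1):
        for ch in b1[p]:
            rows[outgroup].append(GAP)
            rows[in1].append(ch)
            rows[in2].append(GAP)
        for ch in b2[p]:
            rows[outgroup].append(GAP)
            rows[in1].append(GAP)
            rows[in2].append(ch)
        if p < n:
            rows[outgroup].append(out_seq[p])
            rows[in1].append(a1[p])
            rows[in2].append(a2[p])
    return MultiAlignment({k: "".join(v) for k, v in rows.items()})


# ------------------------------------------------------------ variant calls


def _region_of_span(start: int, end: int, features: Sequence[Feature]) -> str:
    """Majority-overlap CDS assignment; ties go to noncoding."""
    span = end - start
    cov = 0
    for f in features:
        if f.kind == "pseudogene":
            continue
        cov += max(0, min(end, f.end) - max(start, f.start))
    return "coding" if cov * 2 > span else "noncoding"


def call_variants(
    aln: MultiAlignment,
    annotations: Sequence[Feature] = (),
    reference: str | None = None,
) -> list[VariantCall]:
    """Call SNP columns and maximal single-genome gap runs (indels).

    ``annotations`` must be in the coordinate system of the ``reference``
    row (default: first row). SNP columns contain ≥2 distinct non-gap
    alleles and no gap; an indel is a maximal gap run confined to exactly
    one genome. Indel region labels use majority overlap with CDS on the
    reference, ties assigned noncoding.
    """
    ids = list(aln.rows)
    if reference is None:
        reference = ids[0]
    mats = {i: np.frombuffer(aln.rows[i].encode(), dtype="S1") for i in ids}
    ncols = aln.ncols
    if ncols == 0:
        return []
    stack = np.stack([mats[i] for i in ids])
    isgap = stack == b"-"
    any_gap = isgap.any(axis=0)
    refpos = aln.col_to_pos(reference)

    variants: list[VariantCall] = []
    # SNPs: gapless columns with >= 2 distinct alleles (multi-allelic columns
    # count once as a polymorphic position)
    cand = np.flatnonzero(~any_gap & (stack != stack[0]).any(axis=0))
    for c in cand:
        alleles = {i: mats[i][c].decode() for i in ids}
        pos = int(refpos[c])
        region = _region_of_span(pos, pos + 1, annotations)
        variants.append(
            VariantCall("SNP", int(c), int(c) + 1, alleles, region, 1, pos)
        )
    # indels: per row, maximal gap runs where all other rows are non-gap
    for gi, i in enumerate(ids):
        g = isgap[gi]
        if not g.any():
            continue
        d = np.diff(g.astype(int))
        starts = list(np.flatnonzero(d == 1) + 1)
        ends = list(np.flatnonzero(d == -1) + 1)
        if g[0]:
            starts = [0] + starts
        if g[-1]:
            ends = ends + [ncols]
        others = [j for j in range(len(ids)) if j != gi]
        for s, e in zip(starts, ends):
            if isgap[others, s:e].any():
                continue  # shared gap region — not a single-genome indel
            length = int(e - s)
            alleles = {j: aln.rows[j][s:e] for j in ids}
            pos = int(refpos[s])
            if i == reference:
                kind = "insertion"  # others carry extra sequence vs reference
                region = _region_of_span(pos, pos + 1, annotations)
            else:
                kind = "deletion"
                region = _region_of_span(pos, pos + length, annotations)
            variants.append(
                VariantCall(kind, int(s), int(e), alleles, region, length, pos, i)
            )
    variants.sort(key=lambda v: v.col_start)
    return variants


def snp_densities(
    variants: Sequence[VariantCall], reference: AnnotatedGenome
) -> dict:
    """SNP and indel densities per kb over the reference genome partition."""
    mask = reference.coding_mask()
    coding_len = int(np.sum(mask))
    total_len = len(reference)
    noncoding_len = total_len - coding_len
    out = {}
    for kind, keys in (("SNP", ("snp",)), (("insertion", "deletion"), ("indel",))):
        kinds = (kind,) if isinstance(kind, str) else kind
        vs = [v for v in variants if v.kind in kinds]
        nc = sum(1 for v in vs if v.region == "coding")
        nn = len(vs) - nc
        key = keys[0]
        out[f"{key}_total"] = len(vs)
        out[f"{key}_coding"] = nc
        out[f"{key}_noncoding"] = nn
        out[f"{key}_per_kb"] = len(vs) / total_len * 1000
        out[f"{key}_coding_per_kb"] = nc / coding_len * 1000 if coding_len else 0.0
        out[f"{key}_noncoding_per_kb"] = (
            nn / noncoding_len * 1000 if noncoding_len else 0.0
        )
    return out


def write_variants_tsv(
    variants: Sequence[VariantCall], path: str | Path, chrom: str = "genome"
) -> None:
    ids = sorted({k for v in variants for k in v.alleles}) if variants else []
    with open(path, "w") as fh:
        cols = ["CHROM", "POS", "KIND", "LEN", "REGION", "GENOME"] + [
            f"ALLELE_{i}" for i in ids
        ]
        fh.write("\t".join(cols) + "\n")
        for v in variants:
            row = [
                chrom,
                str(v.ref_pos + 1),
                v.kind,
                str(v.length),
                v.region,
                v.genome or ".",
            ] + [v.alleles.get(i, ".") for i in ids]
            fh.write("\t".join(row) + "\n")
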