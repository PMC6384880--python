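"""NG86 dN/dS vs an independent enumeration oracle, CAI, group tests."""

import itertools
import math

import numpy as np
import pytest

from endosym import CodonUsageTable, DnDsRecord, cai, group_dnds_summary, ng86_dnds
from endosym.selection import GENETIC_CODE, CodonAlignmentError

# ------------------------------------------------------------------ oracle
# Fully independent NG86 reimplementation: per-codon enumeration of sites
# and of all mutational pathways (equal weighting, stop-passing paths
# skipped), kept deliberately separate from the package internals.

_CODE = dict(GENETIC_CODE)  # the standard code is shared knowledge, not logic


def oracle_sites(codon):
    aa = _CODE[codon]
    s = 0.0
    for pos in range(3):
        alts = [
            codon[:pos] + b + codon[pos + 1 :]
            for b in "ACGT"
            if b != codon[pos]
        ]
        alts = [a for a in alts if _CODE[a] != "*"]
        if alts:
            s += sum(_CODE[a] == aa for a in alts) / len(alts)
    return s, 3.0 - s


def oracle_diffs(c1, c2):
    pos = [i for i in range(3) if c1[i] != c2[i]]
    if not pos:
        return 0.0, 0.0
    results = []
    for order in itertools.permutations(pos):
        cur, sd, nd, blocked = c1, 0, 0, False
        for i in order:
            nxt = cur[:i] + c2[i] + cur[i + 1 :]
            if _CODE[nxt] == "*":
                blocked = True
                break
            if _CODE[nxt] == _CODE[cur]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        if not blocked:
            results.append((sd, nd))
    if not results:
        for order in itertools.permutations(pos):
            cur, sd, nd = c1, 0, 0
            for i in order:
                nxt = cur[:i] + c2[i] + cur[i + 1 :]
                if _CODE[nxt] == _CODE[cur]:
                    sd += 1
                else:
                    nd += 1
                cur = nxt
            results.append((sd, nd))
    sd = sum(r[0] for r in results) / len(results)
    nd = sum(r[1] for r in results) / len(results)
    return sd, nd


def oracle_dnds(s1, s2):
    S = N = Sd = Nd = 0.0
    for i in range(0, len(s1), 3):
        c1, c2 = s1[i : i + 3], s2[i : i + 3]
        if _CODE[c1] == "*" or _CODE[c2] == "*":
            continue
        x1, y1 = oracle_sites(c1)
        x2, y2 = oracle_sites(c2)
        S += (x1 + x2) / 2
        N += (y1 + y2) / 2
        sd, nd = oracle_diffs(c1, c2)
        Sd += sd
        Nd += nd
    ps, pn = Sd / S, Nd / N
    jc = lambda p: -0.75 * math.log(1 - 4 * p / 3)
    return jc(pn), jc(ps)


def random_codon_pair(rng, n_codons, p_mut=0.06):
    sense = [c for c, a in _CODE.items() if a != "*" ]
    c1 = [sense[i] for i in rng.integers(0, len(sense), n_codons)]
    c2 = []
    for c in c1:
        cc = list(c)
        for i in range(3):
            if rng.random() < p_mut:
                cc[i] = "ACGT"[rng.integers(4)]
        cc = "".join(cc)
        c2.append(cc if _CODE[cc] != "*" else c)
    return "".join(c1), "".join(c2)


class TestNg86:
    def test_identical_sequences_flagged(self):
        r = ng86_dnds("ATGGCTAAA", "ATGGCTAAA")
        assert r.dn == 0 and r.ds == 0
        assert r.filtered and r.reason == "ds_too_low"
        assert r.ratio is None

    def test_synonymous_only_changes(self):
        s1 = "ATG" + "GCT" * 5 + "AAA" * 24
        s2 = "ATG" + "GCC" * 5 + "AAA" * 24
        r = ng86_dnds(s1, s2)
        assert r.dn == 0 and r.ds > 0 and not r.filtered

    def test_matches_enumeration_oracle_on_random_pairs(self):
        """Site and difference counts equal the independent per-codon
        pathway enumeration on 100 random 100-codon pairs."""
        rng = np.random.default_rng(8)
        checked = 0
        for _ in range(100):
            s1, s2 = random_codon_pair(rng, 100)
            r = ng86_dnds(s1, s2, ds_window=(0.0, 100.0))
            try:
                dn_o, ds_o = oracle_dnds(s1, s2)
            except ValueError:
                assert r.filtered
                continue
            assert r.dn == pytest.approx(dn_o, abs=1e-12)
            assert r.ds == pytest.approx(ds_o, abs=1e-12)
            checked += 1
        assert checked >= 90

    def test_symmetry_and_concatenation_invariance(self):
        rng = np.random.default_rng(10)
        s1, s2 = random_codon_pair(rng, 60)
        a = ng86_dnds(s1, s2, ds_window=(0.0, 100.0))
        b = ng86_dnds(s2, s1, ds_window=(0.0, 100.0))
        assert a.dn == pytest.approx(b.dn) and a.ds == pytest.approx(b.ds)
        c = ng86_dnds(s1 + s1, s2 + s2, ds_window=(0.0, 100.0))
        assert c.dn == pytest.approx(a.dn) and c.ds == pytest.approx(a.ds)

    def test_ds_window_filters(self):
        s1 = "ATG" + "GCT" * 30
        s2 = "ATG" + "GCC" * 30  # heavily synonymous: ps high
        r = ng86_dnds(s1, s2)
        assert r.filtered and r.reason in ("ds_saturated", "jc_undefined")

    def test_invalid_alignments_rejected(self):
        with pytest.raises(CodonAlignmentError):
            ng86_dnds("ATGA", "ATGA")
        with pytest.raises(CodonAlignmentError):
            ng86_dnds("ATGTAAGCT", "ATGTAAGCT")  # internal stop


class TestGroupSummary:
    def _records(self, values):
        recs, groups = [], {}
        for i, (grp, v) in enumerate(values):
            g = f"g{i}"
            groups[g] = grp
            recs.append(DnDsRecord(g, "p", 0.1, 0.5, v))
        return recs, groups

    def test_identical_values_mean_and_flag(self):
        recs, groups = self._records(
            [("G1", 0.4)] * 3 + [("G2", 0.4)] * 3
        )
        s = group_dnds_summary(recs, groups)
        assert s["group_means"]["G1"] == pytest.approx(0.4)
        assert s["group_means"]["G2"] == pytest.approx(0.4)
        assert s["tests"]["G1_vs_G2"]["flag"] == "zero_variance"
        assert s["tests"]["G1_vs_G2"]["p"] == 1.0

    def test_record_order_invariance(self):
        rng = np.random.default_rng(2)
        vals = [("G1", float(v)) for v in rng.normal(0.4, 0.05, 20)]
        vals += [("G2", float(v)) for v in rng.normal(0.55, 0.05, 20)]
        recs, groups = self._records(vals)
        s1 = group_dnds_summary(recs, groups)
        s2 = group_dnds_summary(list(reversed(recs)), groups)
        assert s1["group_means"] == s2["group_means"]
        assert s1["tests"] == s2["tests"]

    def test_filter_conservation(self):
        recs, groups = self._records([("G1", 0.4)] * 4 + [("G2", 0.5)] * 4)
        recs[0].filtered = True
        recs[0].ratio = None
        s = group_dnds_summary(recs, groups)
        assert s["n_filtered_records"] + s["n_retained_records"] == len(recs)

    def test_empty_group_errors(self):
        recs, groups = self._records([("G1", 0.4)] * 3)
        groups["extra"] = "G2"
        recs.append(DnDsRecord("extra", "p", 0.1, 0.5, 0.5))
        with pytest.raises(ValueError, match="fewer than 2"):
            group_dnds_summary(recs, groups)

    def test_welch_power_at_constructed_effect(self):
        """Welch t-test detects Δ=0.17 at σ=0.05, n=20/group essentially
        always (a smaller-n spot check; the full power sweep runs in the
        acceptance suite)."""
        rng = np.random.default_rng(3)
        hits = 0
        for _ in range(100):
            vals = [("G1", float(v)) for v in rng.normal(0.40, 0.05, 20)]
            vals += [("G2", float(v)) for v in rng.normal(0.57, 0.05, 20)]
            recs, groups = self._records(vals)
            s = group_dnds_summary(recs, groups)
            if s["tests"]["G1_vs_G2"]["p"] < 0.05:
                hits += 1
        assert hits == 100


class TestCai:
    def _usage(self):
        return CodonUsageTable.from_counts(
            {"GCT": 10, "GCC": 5, "GCA": 2, "GCG": 1,
             "AAA": 9, "AAG": 3, "TTT": 8, "TTC": 4}
        )

    def test_optimal_codons_give_one(self):
        u = self._usage()
        assert cai("GCTAAATTT", u) == pytest.approx(1.0)

    def test_single_codon_value(self):
        u = self._usage()
        assert cai("GCC", u) == pytest.approx(0.5)

    def test_met_trp_and_stops_excluded(self):
        u = self._usage()
        assert cai("ATGGCTTGGTAA", u) == pytest.approx(1.0)

    def test_floor_applied_to_zero_w(self):
        u = CodonUsageTable.from_counts({"GCT": 10})
        v = cai("GCA", u, w_floor=0.01)
        assert v == pytest.approx(0.01)

    def test_bounds_and_reorder_invariance(self):
        u = self._usage()
        rng = np.random.default_rng(5)
        cods = ["GCT", "GCC", "GCA", "AAA", "AAG", "TTT", "TTC"]
        seq = [cods[i] for i in rng.integers(0, len(cods), 200)]
        v = cai("".join(seq), u)
        ws = [u.w[c] for c in seq]
        assert min(ws) <= v <= max(ws)
        rng.shuffle(seq)
        assert cai("".join(seq), u) == pytest.approx(v, abs=1e-12)

    def test_log_domain_recomputation_oracle(self):
        """Geometric mean recomputed independently agrees to 1e-12."""
        u = self._usage()
        rng = np.random.default_rng(6)
        sense = [c for c, a in GENETIC_CODE.items() if a != "*"]
        seq = "".join(sense[i] for i in rng.integers(0, len(sense), 1000))
        v = cai(seq, u, w_floor=0.01)
        logs = []
        for i in range(0, len(seq), 3):
            c = seq[i : i + 3]
            aa = GENETIC_CODE[c]
            if aa in ("M", "W", "*"):
                continue
            logs.append(math.log(max(u.w.get(c, 0.0), 0.01)))
        expected = math.exp(math.fsum(logs) / len(logs))
        assert v == pytest.approx(expected, abs=1e-12)
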