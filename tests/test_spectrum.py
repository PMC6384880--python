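"""Polarization rules, spectrum normalization, equilibrium GC, chi-square,
indel direction and homopolymer association."""

import numpy as np
import pytest

from endosym import (
    directional_chi_square,
    equilibrium_gc,
    indel_direction_and_homopolymers,
    load_dated_tree,
    polarize,
    spectrum,
)
from endosym.align import MultiAlignment
from endosym.spectrum import (
    COLLAPSED,
    DIRECTED,
    PolarizedVariant,
    PolarizedVariantSet,
    SpectrumTable,
    collapse_class,
)

from conftest import path_events


def _aln(out, i1, i2):
    return MultiAlignment({"out": out, "i1": i1, "i2": i2})


class TestPolarize:
    def test_outgroup_matches_one_ingroup(self):
        pv = polarize(_aln("ACGT", "ACGT", "AGGT"), ("i1", "i2"), "out")
        (v,) = pv.snps
        assert (v.ancestral, v.derived, v.lineage, v.position) == ("C", "G", "i2", 1)

    def test_three_way_distinct_excluded(self):
        pv = polarize(_aln("AAGT", "ACGT", "AGGT"), ("i1", "i2"), "out")
        assert not pv.snps and pv.n_unpolarizable == 1

    def test_shared_derived_counted_separately(self):
        pv = polarize(_aln("AAAA", "ACAA", "ACAA"), ("i1", "i2"), "out")
        assert not pv.snps and pv.n_shared == 1

    def test_indel_polarization_directions(self):
        # i1 lost 2 bases (outgroup agrees with i2): deletion on i1
        pv = polarize(_aln("AACCTT", "AA--TT", "AACCTT"), ("i1", "i2"), "out")
        (v,) = pv.indels
        assert (v.kind, v.lineage, v.length) == ("del", "i1", 2)
        # i2 gained 3 bases absent from outgroup and i1: insertion on i2
        pv = polarize(_aln("AA---TT", "AA---TT", "AAGGGTT"), ("i1", "i2"), "out")
        (v,) = pv.indels
        assert (v.kind, v.lineage, v.length) == ("ins", "i2", 3)

    def test_polarized_branch_assignment_matches_truth(self, small_ancestor):
        """At low divergence nearly every ingroup difference polarizes onto
        the correct branch; multiple hits cause only a small deficit."""
        from endosym import EvolutionParams, align_pair, evolve_tree, project_threeway

        params = EvolutionParams(
            seed=19, sub_rate=1e-3, indel_rate=0, inversion_rate=0,
            gene_loss_rate_per_phase=(),
        )
        leaves, log = evolve_tree(small_ancestor, params)
        a1 = align_pair(leaves["KR01"], leaves["NZ27"])
        a2 = align_pair(leaves["FK01"], leaves["NZ27"])
        tw = project_threeway(a1, a2, "NZ27")
        pv = polarize(tw, ("KR01", "FK01"), "NZ27")
        # reconstruct the true derived-state bearers: sites where exactly one
        # of KR01/FK01 changed since their common ancestor KF
        per_branch_true = {b: len(log.substitutions(b)) for b in ("KR01", "FK01")}
        assigned = {"KR01": 0, "FK01": 0}
        for v in pv.snps:
            assigned[v.lineage] += 1
        for b in ("KR01", "FK01"):
            # ≥95% accuracy at low divergence (multiple hits cause the slack)
            assert assigned[b] >= 0.95 * per_branch_true[b]
            assert assigned[b] <= 1.02 * per_branch_true[b]


class TestSpectrum:
    def test_uniform_counts_collapse_to_sixths(self):
        pv = PolarizedVariantSet(
            variants=[
                PolarizedVariant(0, x, y, "i1", "SNP")
                for x in "ACGT"
                for y in "ACGT"
                if x != y
            ]
        )
        st = spectrum(pv, "ACGT" * 25)
        for c in COLLAPSED:
            assert st.collapsed_pct[c] == pytest.approx(100 / 6, abs=1e-9)
        assert sum(st.collapsed_pct.values()) == pytest.approx(100, abs=1e-9)

    def test_single_collapsed_class(self):
        pv = PolarizedVariantSet(
            variants=[
                PolarizedVariant(0, "G", "A", "i1", "SNP"),
                PolarizedVariant(1, "C", "T", "i1", "SNP"),
            ]
        )
        st = spectrum(pv, "ACGT" * 10)
        assert st.collapsed_pct["G>A"] == pytest.approx(100.0)
        assert st.n_transitions == 2 and st.n_transversions == 0

    def test_per_site_rates_use_origin_base_frequency(self):
        # 2 G>A changes on a G-poor genome outweigh 2 A>G on an A-rich one
        anc = "G" * 10 + "A" * 90
        pv = PolarizedVariantSet(
            variants=[
                PolarizedVariant(0, "G", "A", "i1", "SNP"),
                PolarizedVariant(1, "G", "A", "i1", "SNP"),
                PolarizedVariant(2, "A", "G", "i1", "SNP"),
                PolarizedVariant(3, "A", "G", "i1", "SNP"),
            ]
        )
        st = spectrum(pv, anc)
        assert st.per_site_rates["G>A"] == pytest.approx(0.2)
        assert st.per_site_rates["A>G"] == pytest.approx(2 / 90)

    def test_zero_frequency_with_observed_changes_errors(self):
        pv = PolarizedVariantSet(
            variants=[PolarizedVariant(0, "G", "A", "i1", "SNP")]
        )
        with pytest.raises(ValueError, match="ancestral"):
            spectrum(pv, "ATAT")

    def test_collapse_class_pairs_complements(self):
        assert collapse_class("C>T") == "G>A"
        assert collapse_class("T>A") == "A>T"
        assert {collapse_class(c) for c in DIRECTED} == set(COLLAPSED)


class TestEquilibriumGC:
    def _table(self, rates):
        full = {c: 0.0 for c in COLLAPSED}
        full.update(rates)
        return SpectrumTable(
            counts={}, ancestral_base_counts={},
            per_site_rates={}, normalized_pct={},
            collapsed_counts={}, collapsed_rates=full, collapsed_pct={},
        )

    def test_two_to_one_bias(self):
        st = self._table({"G>A": 0.2, "A>G": 0.1})
        assert equilibrium_gc(st) == pytest.approx(100 / 3)

    def test_equal_rates(self):
        st = self._table({"G>A": 0.1, "G>T": 0.1, "A>G": 0.1, "A>C": 0.1})
        assert equilibrium_gc(st) == pytest.approx(50.0)

    def test_scale_invariance(self):
        r = {"G>A": 0.23, "G>T": 0.07, "A>G": 0.11, "A>C": 0.02}
        base = equilibrium_gc(self._table(r))
        scaled = equilibrium_gc(self._table({k: 17.3 * v for k, v in r.items()}))
        assert base == pytest.approx(scaled, abs=1e-12)

    def test_both_zero_errors(self):
        with pytest.raises(ValueError, match="undefined"):
            equilibrium_gc(self._table({}))


class TestChiSquare:
    def _table(self, counts, bases):
        full = {c: 0 for c in COLLAPSED}
        full.update(counts)
        return SpectrumTable(
            counts={}, ancestral_base_counts=bases,
            per_site_rates={}, normalized_pct={},
            collapsed_counts=full, collapsed_rates={}, collapsed_pct={},
        )

    def test_balanced_counts_give_zero(self):
        st = self._table(
            {"G>A": 50, "A>G": 50}, {"A": 25, "C": 25, "G": 25, "T": 25}
        )
        stat, p = directional_chi_square(st)
        assert stat == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_hand_computed_statistic(self):
        # counts (100, 50), equal site frequencies:
        # (100-75)^2/75 + (50-75)^2/75 = 50/3
        st = self._table(
            {"G>A": 100, "A>G": 50}, {"A": 25, "C": 25, "G": 25, "T": 25}
        )
        stat, _ = directional_chi_square(st)
        assert stat == pytest.approx(50 / 3)

    def test_zero_total_errors(self):
        st = self._table({}, {"A": 1, "C": 1, "G": 1, "T": 1})
        with pytest.raises(ValueError):
            directional_chi_square(st)

    def test_type_one_error_calibration(self):
        """Unbiased per-site spectrum: rejection rate ≈ α over replicates."""
        rng = np.random.default_rng(20)
        n_g, n_a = 4000, 6000
        alpha, reps = 0.05, 1000
        rejections = 0
        for _ in range(reps):
            n = 200
            # each change originates from a site: GC sites w.p. n_g/(n_g+n_a)
            k_gc = rng.binomial(n, n_g / (n_g + n_a))
            st = self._table(
                {"G>A": int(k_gc), "A>G": int(n - k_gc)},
                {"A": n_a // 2, "T": n_a - n_a // 2,
                 "G": n_g // 2, "C": n_g - n_g // 2},
            )
            _, p = directional_chi_square(st)
            if p < alpha:
                rejections += 1
        se = np.sqrt(alpha * (1 - alpha) / reps)
        assert abs(rejections / reps - alpha) < 3 * se


class TestIndelsAndHomopolymers:
    def test_empty(self):
        n_ins, n_del, net, table = indel_direction_and_homopolymers(
            PolarizedVariantSet(), "ACGT" * 10
        )
        assert (n_ins, n_del, net) == (0, 0, 0)
        assert (table["indel_events"] == 0).all()

    def test_deletion_in_run_assigned_to_run_length_row(self):
        anc = "CG" + "A" * 6 + "GC"
        pv = PolarizedVariantSet(
            variants=[PolarizedVariant(3, "AAAAA", "-----", "i1", "del", 5)]
        )
        n_ins, n_del, net, table = indel_direction_and_homopolymers(pv, anc)
        assert (n_ins, n_del, net) == (0, 1, -5)
        row = table[table.run_length == 6]
        assert int(row["indel_events"].iloc[0]) == 1

    def test_net_bp_direction(self):
        pv = PolarizedVariantSet(
            variants=[
                PolarizedVariant(0, "-", "T", "i1", "ins", 1),
                PolarizedVariant(1, "--", "GG", "i2", "ins", 2),
                PolarizedVariant(2, "ACGTA", "-----", "i1", "del", 5),
            ]
        )
        n_ins, n_del, net, _ = indel_direction_and_homopolymers(pv, "ACGT" * 5)
        assert (n_ins, n_del, net) == (2, 1, -2)

    def test_slippage_simulation_monotone_events_per_run(self, small_ancestor):
        """Polarized indels from a slippage-heavy simulation concentrate in
        long ancestral runs (positive Spearman trend)."""
        from scipy.stats import spearmanr

        from endosym import EvolutionParams, align_pair, evolve_tree, project_threeway

        params = EvolutionParams(
            seed=31, sub_rate=5e-4, indel_rate=4e-4, slippage_multiplier=2.2,
            inversion_rate=0, gene_loss_rate_per_phase=(),
            indel_class_weights=(1.0, 0.0, 0.0, 0.0), cds_indel_factor=1.0,
        )
        leaves, _ = evolve_tree(small_ancestor, params)
        a1 = align_pair(leaves["KR01"], leaves["NZ27"], band=32)
        a2 = align_pair(leaves["FK01"], leaves["NZ27"], band=32)
        tw = project_threeway(a1, a2, "NZ27")
        pv = polarize(tw, ("KR01", "FK01"), "NZ27")
        assert len(pv.indels) > 100
        _, _, _, table = indel_direction_and_homopolymers(
            pv, tw.ungapped("NZ27")
        )
        sub = table[(table.n_runs >= 30)]
        rho, p = spearmanr(sub.run_length, sub.events_per_run)
        assert rho > 0.7 and p < 0.05
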