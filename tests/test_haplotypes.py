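"""Founder-mosaic classifier: compatibility, parsimony DP, spectra, flanks."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import mhcrec as M

from conftest import brute_force_min_switches, compat_from_matrix, random_compat_instance


def _chimera(founders, panel, left, right, cut):
    a = founders.haplotype_of(left, panel).alleles
    b = founders.haplotype_of(right, panel).alleles
    return M.HaplotypeObservation(a[:cut] + b[cut:])


class TestCompatibility:
    def test_private_allele_points_to_one_founder(self, panel, founders):
        hap = founders.haplotype_of("H5", panel)
        compat = M.build_compatibility(panel, founders, hap)
        i = panel.index("D6S2854")
        assert hap.alleles[i] == 213
        assert [founders.founders[j] for j in np.flatnonzero(compat.matrix[i])] == ["H5"]

    def test_shared_allele_matches_the_sharing_founders(self, panel, founders):
        hap = founders.haplotype_of("H1", panel)
        compat = M.build_compatibility(panel, founders, hap)
        i = panel.index("D6S2847")
        assert hap.alleles[i] == 321
        hits = [founders.founders[j] for j in np.flatnonzero(compat.matrix[i])]
        assert hits == ["H1", "H2", "H3", "H4", "H5"]

    def test_missing_allele_is_uninformative(self, panel, founders):
        alleles = list(founders.haplotype_of("H1", panel).alleles)
        alleles[3] = None
        compat = M.build_compatibility(panel, founders, M.HaplotypeObservation(tuple(alleles)))
        assert compat.matrix[3].all()

    def test_length_mismatch_rejected(self, panel, founders):
        with pytest.raises(ValueError, match="panel"):
            M.build_compatibility(panel, founders, M.HaplotypeObservation((129,)))

    def test_unknown_allele_flags_orphan(self, panel, founders):
        alleles = list(founders.haplotype_of("H1", panel).alleles)
        alleles[0] = 9999
        compat = M.build_compatibility(panel, founders, M.HaplotypeObservation(tuple(alleles)))
        assert compat.orphan[0] and not compat.orphan[1:].any()


class TestMinRecombinations:
    def test_every_founder_is_its_own_zero_switch_mosaic(self, panel, founders):
        for f in founders.founders:
            compat = M.build_compatibility(panel, founders, founders.haplotype_of(f, panel))
            dec = M.min_recombinations(compat)
            assert dec.h == 0
            assert f in dec.segments[0][1]

    def test_single_chimera_needs_one_switch(self, panel, founders):
        hap = _chimera(founders, panel, "H1", "H2", 9)
        compat = M.build_compatibility(panel, founders, hap)
        dec = M.min_recombinations(compat)
        assert dec.h == brute_force_min_switches(compat.matrix) == 1
        assert "H1" in dec.segments[0][1] and "H2" in dec.segments[-1][1]

    def test_fully_shared_alleles_leave_all_founders_candidate(self):
        mat = np.ones((5, 3), dtype=bool)
        dec = M.min_recombinations(compat_from_matrix(mat))
        assert dec.h == 0
        assert dec.segments[0][1] == frozenset({"F0", "F1", "F2"})

    @pytest.mark.parametrize("case", range(200))
    def test_dp_matches_exhaustive_enumeration(self, case):
        rng = np.random.default_rng(7000 + case)
        mat = random_compat_instance(rng)
        dec = M.min_recombinations(compat_from_matrix(mat))
        if dec.h <= 4:
            assert dec.h == brute_force_min_switches(mat)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), drop=st.integers(0, 7))
    def test_removing_a_marker_never_raises_h(self, seed, drop):
        rng = np.random.default_rng(seed)
        mat = random_compat_instance(rng)
        full = M.min_recombinations(compat_from_matrix(mat)).h
        reduced_mat = np.delete(mat, drop % mat.shape[0], axis=0)
        if reduced_mat.shape[0] >= 1:
            reduced = M.min_recombinations(compat_from_matrix(reduced_mat)).h
            assert reduced <= full

    def test_orphan_policies(self, panel, founders):
        alleles = list(founders.haplotype_of("H1", panel).alleles)
        alleles[5] = 9999
        hap = M.HaplotypeObservation(tuple(alleles))
        compat = M.build_compatibility(panel, founders, hap)
        dec = M.min_recombinations(compat, policy="mutation")
        assert dec.h == 0 and dec.orphan_markers == (panel.markers[5],)
        dec_w = M.min_recombinations(compat, policy="wildcard")
        assert dec_w.h == 0 and dec_w.orphan_markers == ()
        with pytest.raises(ValueError, match="no founder"):
            M.min_recombinations(compat, policy="error")

    def test_breakpoint_intervals_admit_every_interior_placement(self, panel, founders, rng):
        """Any gap inside a reported interval supports an equally parsimonious mosaic."""
        names = list(founders.founders)
        checked = 0
        for _ in range(100):
            left, right = rng.choice(names, size=2, replace=False)
            cut = int(rng.integers(1, len(panel)))
            hap = _chimera(founders, panel, left, right, cut)
            compat = M.build_compatibility(panel, founders, hap)
            dec = M.min_recombinations(compat)
            mat = compat.matrix.copy()
            mat[compat.orphan] = True
            for (seg_l, _), (seg_r, cands_r), (lo, hi) in zip(
                dec.segments, dec.segments[1:], dec.breakpoints
            ):
                for g in range(lo, hi):
                    left_ok = mat[seg_l[0] : g + 1].all(axis=0).any()
                    right_ok = mat[g + 1 : seg_r[1]].all(axis=0).any()
                    assert left_ok and right_ok
                    checked += 1
        assert checked > 0


class TestClassifyPopulation:
    def test_counts_sum_over_haplotypes(self, panel, founders):
        chim = _chimera(founders, panel, "H1", "H2", 9)
        haps = [founders.haplotype_of("H1", panel)] * 4 + [chim] * 2
        result = M.classify_population(panel, founders, haps)
        assert result.spectrum.counts == (4, 2)
        assert result.spectrum.n == 6
        assert result.distinct_types == {0: 1, 1: 1}

    def test_empty_input_rejected(self, panel, founders):
        with pytest.raises(ValueError, match="no haplotypes"):
            M.classify_population(panel, founders, [])

    def test_mostly_missing_haplotype_rejected(self, panel, founders):
        alleles = [None] * len(panel)
        alleles[0] = 129
        with pytest.raises(ValueError, match="missing"):
            M.classify_population(
                panel, founders, [M.HaplotypeObservation(tuple(alleles))]
            )


class TestFlankingDistribution:
    def test_single_recombinant_flanks(self, panel, founders):
        chim = _chimera(founders, panel, "H1", "H2", 9)
        result = M.classify_population(panel, founders, [chim] * 10)
        telo = M.flanking_founder_distribution(
            result.decompositions, "telomeric", founders.founders
        )
        cent = M.flanking_founder_distribution(
            result.decompositions, "centromeric", founders.founders
        )
        assert telo.tolist() == [10, 0, 0, 0, 0, 0, 0]
        assert cent.tolist() == [0, 10, 0, 0, 0, 0, 0]

    def test_central_requires_double_recombinants(self, panel, founders):
        chim = _chimera(founders, panel, "H1", "H2", 9)
        result = M.classify_population(panel, founders, [chim])
        with pytest.raises(ValueError, match="double"):
            M.flanking_founder_distribution(
                result.decompositions, "central", founders.founders
            )

    def test_tie_policies_on_ambiguous_flank(self):
        mat = np.zeros((4, 3), dtype=bool)
        mat[:2, [0, 1]] = True  # telomeric side shared by F0 and F1
        mat[2:, 2] = True  # centromeric side unique to F2
        dec = M.min_recombinations(compat_from_matrix(mat))
        assert dec.h == 1
        frac = M.flanking_founder_distribution(
            [dec], "telomeric", ("F0", "F1", "F2"), tie_policy="fractional"
        )
        assert frac.sum() == pytest.approx(1.0)
        assert frac.tolist() == pytest.approx([0.5, 0.5, 0.0])
        drop = M.flanking_founder_distribution(
            [dec], "telomeric", ("F0", "F1", "F2"), tie_policy="drop"
        )
        assert drop.sum() == 0.0

    def test_simulated_recombinants_look_uniform_from_uniform_founders(
        self, panel, founders
    ):
        """Equal-frequency founder chimeras give a flat flank distribution."""
        rng = np.random.default_rng(5)
        names = list(founders.founders)
        haps = []
        for _ in range(700):
            left, right = rng.choice(names, size=2, replace=False)
            cut = int(rng.integers(4, len(panel) - 3))
            haps.append(_chimera(founders, panel, left, right, cut))
        result = M.classify_population(panel, founders, haps)
        singles = [d for d in result.decompositions if d.h == 1]
        telo = M.flanking_founder_distribution(singles, "telomeric", names)
        stat, df, p = M.homogeneity_chi2(telo, np.full(7, 1 / 7))
        assert df == 6
        assert p > 0.01


class TestHomogeneityChi2:
    def test_proportional_counts_give_zero(self):
        stat, df, p = M.homogeneity_chi2([5, 5, 5, 5], [0.25] * 4)
        assert stat == pytest.approx(0.0)
        assert df == 3
        assert p == pytest.approx(1.0)

    def test_hand_computed_statistic(self):
        stat, df, p = M.homogeneity_chi2([10, 0], [0.5, 0.5])
        assert stat == pytest.approx(10.0)
        assert df == 1

    def test_zero_reference_with_mass_rejected(self):
        with pytest.raises(ValueError, match="zero-frequency"):
            M.homogeneity_chi2([1, 1], [1.0, 0.0])


class TestNaivePhase:
    def test_founder_anchored_genotype_round_trips(self, panel, founders):
        h1 = founders.haplotype_of("H1", panel)
        chim = _chimera(founders, panel, "H3", "H4", 8)
        pairs = tuple(zip(h1.alleles, chim.alleles))
        rec = M.GenotypeRecord("a1", pairs)
        phased = M.naive_phase(panel, founders, rec)
        assert phased is not None
        got = {phased[0].alleles, phased[1].alleles}
        assert got == {h1.alleles, chim.alleles}
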