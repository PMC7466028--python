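"""DNase I digestion: fragment enumeration, peak matching, footprinting."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from oligopep import digestor as dg
from oligopep import massbook as mb
from oligopep import synthkit
from oligopep.errors import MatchingError, ProfileError


class TestEnumerateFragments:
    @pytest.mark.parametrize("n", [1, 2, 3, 10, 17, 50])
    def test_fragment_count(self, n):
        oligo = mb.ModifiedOligo("x", "ACGT" * (n // 4 + 1))
        oligo = mb.ModifiedOligo("x", oligo.sequence[:n])
        frags = dg.enumerate_fragments(oligo)
        assert len(frags) == n * (n + 1) // 2
        assert len({(f.start, f.end) for f in frags}) == len(frags)

    def test_full_length_fragment_equals_parent(self, ssa):
        frag = dg.fragment_oligo(ssa, 1, len(ssa))
        assert frag.oligo.five_prime == ssa.five_prime
        assert frag.oligo.three_prime == ssa.three_prime
        for scale in ("average", "monoisotopic"):
            assert frag.neutral_mass(scale) == pytest.approx(
                mb.oligo_neutral_mass(ssa, scale), abs=1e-9
            )

    def test_internal_fragment_chemistry(self, ssa):
        inner = dg.fragment_oligo(ssa, 3, 9)
        assert inner.oligo.five_prime == "phosphate"
        assert inner.oligo.three_prime == "OH"
        lead = dg.fragment_oligo(ssa, 1, 9)
        assert lead.oligo.five_prime == "OH"  # parent 5' end retained

    def test_modifications_carried_into_fragments(self):
        parent = mb.ssdna_a_star()  # alkyne on position 4
        with_mod = dg.fragment_oligo(parent, 2, 6)
        without = dg.fragment_oligo(mb.ssdna_a(), 2, 6)
        delta = with_mod.neutral_mass("average") - without.neutral_mass("average")
        assert delta == pytest.approx(mb.EC("C8H8").mass("average"), abs=1e-9)
        assert dg.fragment_oligo(parent, 6, 12).oligo.modifications == ()

    def test_hydrolysis_mass_conservation_all_splits(self):
        """Cutting any fragment adds one water: masses balance exactly."""
        parent = mb.ModifiedOligo("x", "GCATCGGATC")  # 10-mer
        n = len(parent)
        for scale in ("average", "monoisotopic"):
            water = mb.WATER.mass(scale)
            for s in range(1, n + 1):
                for e in range(s, n + 1):
                    whole = dg.fragment_oligo(parent, s, e).neutral_mass(scale)
                    for p in range(s, e):
                        left = dg.fragment_oligo(parent, s, p).neutral_mass(scale)
                        right = dg.fragment_oligo(parent, p + 1, e).neutral_mass(scale)
                        assert left + right == pytest.approx(
                            whole + water, abs=1e-6
                        )

    def test_invalid_span_rejected(self, ssa):
        with pytest.raises(ProfileError):
            dg.fragment_oligo(ssa, 5, 3)
        with pytest.raises(ProfileError):
            dg.fragment_oligo(ssa, 0, 3)


class TestMatchPeaks:
    def test_round_trip_with_ppm_offset(self, ssa):
        frags = dg.enumerate_fragments(ssa)
        target = next(f for f in frags if (f.start, f.end) == (5, 10))
        (_, mz3), = mb.mz_for_charges(target.neutral_mass(), [3])
        peaks = dg.PeakList(mz=[mz3 * (1 + 5e-6)], area=[100.0])
        (a,) = dg.match_peaks(peaks, frags, tol_ppm=25.0)
        spans = {(c.fragment.start, c.fragment.end, c.z) for c in a.candidates}
        assert (5, 10, 3) in spans
        ppm = next(c.ppm_error for c in a.candidates if c.z == 3)
        assert ppm == pytest.approx(5.0, abs=0.1)

    def test_low_mz_peak_unassigned(self, ssa):
        frags = dg.enumerate_fragments(ssa)
        (a,) = dg.match_peaks(dg.PeakList(mz=[50.0], area=[1.0]), frags)
        assert not a.assigned

    def test_empty_fragment_list_rejected(self):
        with pytest.raises(MatchingError):
            dg.match_peaks(dg.PeakList(mz=[100.0], area=[1.0]), [])

    def test_nonpositive_tolerance_rejected(self, ssa):
        with pytest.raises(MatchingError):
            dg.match_peaks(
                dg.PeakList(mz=[100.0], area=[1.0]),
                dg.enumerate_fragments(ssa),
                tol_ppm=0.0,
            )

    def test_isobaric_fragments_share_a_group(self):
        # internal AC at (2,3) and CA at (6,7): same composition
        parent = mb.ModifiedOligo("x", "GACTTCAG")
        frags = dg.enumerate_fragments(parent)
        ac = next(f for f in frags if (f.start, f.end) == (2, 3))
        ca = next(f for f in frags if (f.start, f.end) == (6, 7))
        assert ac.composition().counts == ca.composition().counts
        (_, mz1), = mb.mz_for_charges(ac.neutral_mass(), [1])
        (a,) = dg.match_peaks(dg.PeakList(mz=[mz1], area=[10.0]), frags)
        z1 = [(c, g) for c, g in zip(a.candidates, a.group_ids) if c.z == 1]
        spans = {(c.fragment.start, c.fragment.end) for c, _ in z1}
        assert {(2, 3), (6, 7)} <= spans
        assert len({g for _, g in z1}) == 1  # one ambiguity group

    def test_brute_force_composition_groups(self, ssa):
        """Group ids coincide exactly with elemental-composition identity."""
        frags = dg.enumerate_fragments(ssa)
        (_, mz1), = mb.mz_for_charges(frags[0].neutral_mass(), [1])
        peaks = dg.PeakList(mz=[mz1], area=[1.0])
        assignments = dg.match_peaks(peaks, frags, tol_ppm=25.0)
        for a in assignments:
            for (c1, g1) in zip(a.candidates, a.group_ids):
                for (c2, g2) in zip(a.candidates, a.group_ids):
                    same_comp = (
                        c1.fragment.composition().counts
                        == c2.fragment.composition().counts
                    )
                    assert (g1 == g2) == same_comp


class TestProfiles:
    def test_single_leading_fragment_is_indicator_on_its_bond(self, ssa):
        frags = dg.enumerate_fragments(ssa)
        lead = next(f for f in frags if (f.start, f.end) == (1, 7))
        a = dg.Assignment(0, 500.0, 42.0, [dg.Candidate(lead, 3, 0.0)], [0])
        prof = dg.build_profile([a], ssa, "per_bond")
        expected = np.zeros(len(ssa) - 1)
        expected[6] = 1.0  # bond 7
        np.testing.assert_allclose(prof.values, expected)

    def test_ambiguity_group_splits_area_equally(self, ssa):
        frags = dg.enumerate_fragments(ssa)
        f1 = next(f for f in frags if (f.start, f.end) == (1, 7))
        f2 = next(f for f in frags if (f.start, f.end) == (1, 4))
        a = dg.Assignment(
            0, 500.0, 10.0,
            [dg.Candidate(f1, 3, 0.0), dg.Candidate(f2, 2, 0.0)],
            [0, 1],
        )
        prof = dg.build_profile([a], ssa, "per_bond")
        assert prof.values[6] == pytest.approx(0.5)
        assert prof.values[3] == pytest.approx(0.5)

    def test_per_length_profile(self, ssa):
        frags = dg.enumerate_fragments(ssa)
        f = next(fr for fr in frags if (fr.start, fr.end) == (5, 10))
        a = dg.Assignment(0, 500.0, 7.0, [dg.Candidate(f, 3, 0.0)], [0])
        prof = dg.build_profile([a], ssa, "per_length")
        assert prof.values[5] == pytest.approx(1.0)  # length 6

    def test_profiles_are_probability_vectors(self, ssa):
        peaks = synthkit.simulate_digest_peaks(synthkit.DigestConfig(), 11)
        assignments = dg.match_peaks(peaks, dg.enumerate_fragments(ssa))
        for mode in ("per_bond", "per_length"):
            prof = dg.build_profile(assignments, ssa, mode)
            assert np.all(prof.values >= 0)
            assert prof.values.sum() == pytest.approx(1.0)

    def test_uniform_digest_gives_uniform_cut_counts(self, ssa):
        """Sampling oracle: uniform propensities -> multinomial cut counts."""
        cfg = synthkit.DigestConfig(n_events=10_000)
        census, cuts = synthkit.sample_fragment_census(cfg, 5)
        n = len(ssa)
        counts = np.zeros(n - 1)
        for (s, e), c in census.items():
            if s > 1:
                counts[s - 2] += c
            if e < n:
                counts[e - 1] += c
        counts /= counts.sum()
        p = 1.0 / (n - 1)
        n_cuts = int(cuts.sum())
        sigma = np.sqrt(p * (1 - p) / n_cuts)
        assert np.all(np.abs(counts - p) < 3.5 * sigma)

    def test_uniform_digest_profile_uniform_up_to_isobar_smearing(self, ssa):
        """The matched per-bond profile is uniform apart from the documented
        bias of splitting peak areas equally across composition isobars."""
        cfg = synthkit.DigestConfig(ppm_sigma=0.0, area_cv=0.0, n_events=10_000)
        peaks = synthkit.simulate_digest_peaks(cfg, 5)
        assignments = dg.match_peaks(peaks, dg.enumerate_fragments(ssa))
        prof = dg.build_profile(assignments, ssa, "per_bond")
        assert np.all(np.abs(prof.values - 1.0 / 16) < 0.04)

    def test_no_assignments_rejected(self, ssa):
        with pytest.raises(ProfileError):
            dg.build_profile([], ssa)
        unassigned = dg.Assignment(0, 50.0, 1.0)
        with pytest.raises(ProfileError):
            dg.build_profile([unassigned], ssa)


class TestProtection:
    def _uniform(self, n_bonds, parent_id="ssDNA A"):
        return dg.CleavageProfile(
            parent_id, "per_bond", np.full(n_bonds, 1.0 / n_bonds)
        )

    def test_identical_profiles_score_zero(self):
        a, b = self._uniform(16), self._uniform(16)
        np.testing.assert_allclose(dg.protection_score(a, b), 0.0)

    def test_zeroed_window_scores_negative_exactly_there(self):
        free = self._uniform(16)
        vals = free.values.copy()
        vals[4:9] = 0.0  # bonds 5..9
        vals /= vals.sum()
        bound = dg.CleavageProfile("ssDNA A", "per_bond", vals)
        s = dg.protection_score(free, bound)
        assert np.all(s[4:9] < 0)
        assert np.all(s[:4] > 0) and np.all(s[9:] > 0)  # renormalized up

    def test_zero_pseudocount_with_zero_bin_rejected(self):
        free = self._uniform(16)
        vals = free.values.copy()
        vals[0] = 0.0
        bound = dg.CleavageProfile("ssDNA A", "per_bond", vals)
        with pytest.raises(ProfileError):
            dg.protection_score(free, bound, pseudocount=0.0)

    def test_mismatched_parents_rejected(self):
        with pytest.raises(ProfileError):
            dg.protection_score(
                self._uniform(16, "ssDNA A"), self._uniform(16, "ssDNA B")
            )

    def test_all_zero_scores_no_window(self):
        call = dg.call_protected_window(np.zeros(16))
        assert call.window is None and not call.protected

    def test_longest_run_wins(self):
        scores = np.zeros(16)
        scores[2:5] = -2.0  # run of 3
        scores[8:13] = -1.5  # run of 5
        call = dg.call_protected_window(scores, threshold=-1.0, min_run=3)
        assert call.window == (9, 13)

    def test_tie_broken_by_most_negative_mean(self):
        scores = np.zeros(16)
        scores[1:4] = -1.5
        scores[10:13] = -3.0
        call = dg.call_protected_window(scores, threshold=-1.0, min_run=3)
        assert call.window == (11, 13)

    def test_min_run_filters_short_runs(self):
        scores = np.zeros(16)
        scores[5:7] = -5.0
        call = dg.call_protected_window(scores, threshold=-1.0, min_run=3)
        assert call.window is None


class TestFootprintEndToEnd:
    def test_planted_mask_recovered(self, ssa):
        free = synthkit.simulate_digest_peaks(synthkit.DigestConfig(), 1)
        bound = synthkit.simulate_digest_peaks(
            synthkit.gcre_protected_digest_config(), 1001
        )
        call = dg.footprint(free, bound, ssa)
        assert call.window == (5, 9)

    def test_no_mask_no_window(self, ssa):
        free = synthkit.simulate_digest_peaks(synthkit.DigestConfig(), 7)
        bound = synthkit.simulate_digest_peaks(
            synthkit.DigestConfig(label="bound"), 2007
        )
        call = dg.footprint(free, bound, ssa)
        assert call.window is None


@given(st.integers(min_value=1, max_value=30))
@settings(max_examples=30, deadline=None)
def test_fragment_count_property(n):
    seq = ("ACGT" * ((n + 3) // 4))[:n]
    assert len(dg.enumerate_fragments(mb.ModifiedOligo("x", seq))) == n * (n + 1) // 2
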