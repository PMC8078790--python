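"""Report surface: summaries, maps, histograms, asymmetry, normalisation."""

import numpy as np
import pytest

import nickseq as nk
from nickseq.align import MutationEvent
from nickseq.profiler import (
    CoverageInputs,
    NormalizationError,
    PositionProfile,
    asymmetry_bootstrap_ci,
    is_transversion,
)


def D(start, length):
    return MutationEvent(kind="deletion", start=start, length=length)


def S(pos, ref, alt):
    return MutationEvent(kind="snv", start=pos, ref_base=ref, alt_base=alt)


def I1(start, base="G", amb=None):
    lo, hi = amb if amb else (start, start)
    return MutationEvent(kind="insertion", start=start, length=0, inserted=base,
                         amb_start=lo, amb_end=hi)


class TestConditionSummary:
    def test_plain_fractions(self, call_factory):
        calls = [call_factory([D(140, 3)]) for _ in range(10)]
        calls += [call_factory() for _ in range(90)]
        s = nk.condition_summary(calls)
        assert s.n_molecules == 100
        assert s.freq_mutant == pytest.approx(0.10)
        assert s.freq_deletion == pytest.approx(0.10)
        assert s.subtracted["deletion"] == pytest.approx(0.10)

    def test_background_subtraction_floors_at_zero(self, call_factory):
        calls = [call_factory([S(150, "C", "A")]) for _ in range(2)]
        calls += [call_factory() for _ in range(998)]
        s = nk.condition_summary(calls, background={"snv": 0.0026})
        assert s.freq_snv == pytest.approx(0.002)
        assert s.subtracted["snv"] == 0.0

    def test_subtraction_is_monotone_in_background(self, call_factory):
        calls = [call_factory([S(150, "C", "A")]) for _ in range(50)]
        calls += [call_factory() for _ in range(950)]
        subs = [
            nk.condition_summary(calls, background={"snv": b}).subtracted["snv"]
            for b in (0.0, 0.01, 0.04, 0.06, 0.2)
        ]
        assert subs == sorted(subs, reverse=True)
        assert all(0.0 <= x <= 1.0 for x in subs)

    def test_transversion_classification_and_fraction(self, call_factory):
        assert is_transversion("G", "T") and is_transversion("A", "C")
        assert not is_transversion("A", "G") and not is_transversion("C", "T")
        calls = [
            call_factory([S(150, "G", "T")]),
            call_factory([S(151, "A", "C")]),
            call_factory([S(152, "C", "T")]),
            call_factory([S(153, "A", "G")]),
        ]
        s = nk.condition_summary(calls)
        assert s.transversion_fraction == pytest.approx(0.5)

    def test_event_counting_option(self, call_factory):
        calls = [call_factory([S(150, "C", "A"), S(160, "G", "T")])]
        calls += [call_factory() for _ in range(9)]
        by_mol = nk.condition_summary(calls)
        by_ev = nk.condition_summary(calls, count="events")
        assert by_mol.freq_snv == pytest.approx(0.1)
        assert by_ev.freq_snv == pytest.approx(0.2)

    def test_empty_call_set_is_error(self):
        with pytest.raises(ValueError):
            nk.condition_summary([])

    def test_excluded_molecules_shrink_no_denominator(self, call_factory):
        good = [call_factory([D(160, 2)])] + [call_factory() for _ in range(9)]
        with_bad = good + [call_factory([], discordant=True)]
        assert (
            nk.condition_summary(with_bad).freq_deletion
            == nk.condition_summary(good).freq_deletion
        )


class TestMaps:
    def test_no_deletions_all_zero(self, call_factory, window, amplicon):
        prof = nk.fractional_decrease_map([call_factory() for _ in range(5)],
                                          window, amplicon)
        assert prof.frac_lost.sum() == 0.0

    def test_single_deletion_footprint(self, call_factory, site, window, amplicon):
        cut = site.cut
        calls = [call_factory([D(cut - 2, 5)])] + [call_factory() for _ in range(9)]
        prof = nk.fractional_decrease_map(calls, window, amplicon)
        lost = dict(zip(prof.positions, prof.frac_lost))
        for pos in range(cut - 2, cut + 3):
            assert lost[pos] == pytest.approx(0.1)
        assert prof.frac_lost.sum() == pytest.approx(0.5)

    def test_map_integrates_to_deleted_base_total(self, call_factory, window, amplicon):
        calls = [call_factory([D(150, 4)]), call_factory([D(160, 7)]), call_factory()]
        prof = nk.fractional_decrease_map(calls, window, amplicon)
        assert prof.deleted.sum() == 11

    def test_snv_spectrum_counts(self, call_factory, window, amplicon):
        pos = window.start + 5
        ref_b = amplicon.sequence[pos]
        alt = "A" if ref_b != "A" else "C"
        calls = [call_factory([S(pos, ref_b, alt)])] + [call_factory()]
        prof = nk.snv_spectrum_map(calls, window, amplicon)
        col = "ACGT".index(alt)
        assert prof.alt_counts[pos - window.start, col] == 1
        assert prof.alt_counts.sum() == 1


class TestHistograms:
    def test_single_1bp_deletion(self, call_factory):
        h = nk.deletion_length_histogram([call_factory([D(150, 1)])])
        assert h.fine[1] == 1 and h.decades[(1, 10)] == 1 and h.max_length == 1

    def test_empty(self, call_factory):
        h = nk.deletion_length_histogram([call_factory()])
        assert sum(h.fine.values()) == 0 and h.total == 0

    def test_decade_binning(self, call_factory):
        calls = [call_factory([D(140, L)]) for L in (3, 10, 11, 25)]
        h = nk.deletion_length_histogram(calls)
        assert h.decades == {(1, 10): 2, (11, 20): 1, (21, 30): 1}
        assert h.fine[3] == 1
        assert sum(h.fine.values()) <= h.total

    def test_insertion_lengths(self, call_factory):
        calls = [call_factory([I1(166)]), call_factory([I1(166, base="GG")])]
        h = nk.insertion_length_histogram(calls)
        assert h.fine[1] == 1 and h.fine[2] == 1


class TestInsertionComposition:
    def test_pure_plus_one_g(self, call_factory, site, amplicon):
        calls = [call_factory([I1(site.cut, amb=(site.cut, site.cut + 2))])
                 for _ in range(5)]
        comp = nk.insertion_composition(calls, site, amplicon)
        assert comp.base_counts == {"G": 5}
        # +1 position in the edited molecule is the inserted G; -1 is the T
        assert comp.flank_counts["+1"] == {"G": 5}
        assert comp.flank_counts["-1"] == {"T": 5}

    def test_empty(self, call_factory, site, amplicon):
        comp = nk.insertion_composition([call_factory()], site, amplicon)
        assert comp.base_counts == {}

    def test_mixture_recovered_within_binomial_se(self, site, amplicon, call_factory):
        rng = np.random.default_rng(61)
        n = 2000
        bases = rng.choice(["G", "T"], size=n)
        calls = [call_factory([I1(site.cut, base=b, amb=(site.cut, site.cut))])
                 for b in bases]
        comp = nk.insertion_composition(calls, site, amplicon)
        frac_g = comp.base_counts["G"] / n
        se = np.sqrt(0.25 / n)
        assert abs(frac_g - 0.5) < 3 * se


class TestAsymmetry:
    def _profile(self, window, amplicon, deleted):
        w = window.width
        return PositionProfile(
            window=window,
            ref=amplicon.sequence[window.start:window.end],
            covering=np.full(w, 100),
            deleted=np.asarray(deleted),
            alt_counts=np.zeros((w, 4), dtype=int),
        )

    def test_mirrored_profile_gives_zero(self, site, window, amplicon):
        w = window.width
        cut_i = site.cut - window.start
        deleted = np.zeros(w, dtype=int)
        deleted[cut_i - 5 : cut_i] = 7
        deleted[cut_i : cut_i + 5] = 7
        prof = self._profile(window, amplicon, deleted)
        assert nk.asymmetry_index(prof, site.cut) == 0.0

    def test_all_mass_3prime_gives_plus_one(self, site, window, amplicon):
        deleted = np.zeros(window.width, dtype=int)
        deleted[site.cut - window.start + 3] = 10
        prof = self._profile(window, amplicon, deleted)
        assert nk.asymmetry_index(prof, site.cut) == 1.0

    def test_empty_profile_returns_zero_with_warning(self, site, window, amplicon, caplog):
        prof = self._profile(window, amplicon, np.zeros(window.width, dtype=int))
        with caplog.at_level("WARNING"):
            assert nk.asymmetry_index(prof, site.cut) == 0.0
        assert "undefined" in caplog.text

    def test_bootstrap_ci_excludes_zero_for_skewed_calls(self, call_factory, site, window):
        calls = [call_factory([D(site.cut, 10)]) for _ in range(60)]
        calls += [call_factory([D(site.cut - 5, 5)]) for _ in range(20)]
        lo, hi = asymmetry_bootstrap_ci(calls, window, site.cut,
                                        rng=np.random.default_rng(3))
        assert lo > 0.0


class TestDualSite:
    def _windows(self, amplicon):
        a = nk.ScoringWindow(151, 181)  # 30 bp around cut 166
        b = nk.ScoringWindow(116, 146)  # 30 bp around cut 131
        return a, b

    def test_overlapping_windows_rejected(self, call_factory, amplicon):
        with pytest.raises(ValueError):
            nk.dual_site_partition([call_factory()], nk.ScoringWindow(100, 150),
                                   nk.ScoringWindow(140, 180))

    def test_single_site_molecules(self, call_factory, amplicon):
        a, b = self._windows(amplicon)
        calls = [call_factory([D(166, 3)]), call_factory([D(131, 2)]), call_factory()]
        assert nk.dual_site_partition(calls, a, b) == {
            "a_only": 1, "b_only": 1, "both": 0, "neither": 0}

    def test_events_only_at_one_site_never_count_both(self, call_factory, amplicon):
        a, b = self._windows(amplicon)
        calls = [call_factory([D(160 + i, 4)]) for i in range(5)]
        part = nk.dual_site_partition(calls, a, b)
        assert part["both"] == 0 and part["a_only"] == 5

    def test_independent_co_editing_matches_product_expectation(self, call_factory, amplicon):
        """Co-nicking with independent low per-site rates: the 'both' fraction
        matches p_a * p_b within 3 SE."""
        a, b = self._windows(amplicon)
        rng = np.random.default_rng(67)
        n, pa, pb = 20_000, 0.05, 0.04
        calls = []
        for _ in range(n):
            evs = []
            if rng.random() < pa:
                evs.append(D(166 - int(rng.integers(0, 5)), int(rng.integers(1, 6))))
            if rng.random() < pb:
                evs.append(D(131 - int(rng.integers(0, 5)), int(rng.integers(1, 6))))
            calls.append(call_factory(evs))
        part = nk.dual_site_partition(calls, a, b)
        frac_both = part["both"] / n
        exp = pa * pb
        se = np.sqrt(exp * (1 - exp) / n)
        assert abs(frac_both - exp) < 3 * se


class TestNormalisationAndCoverage:
    def test_condition_equal_reference_is_one(self):
        assert nk.normalize_snv_frequencies(0.02, 0.02, 0.0026) == pytest.approx(1.0)

    def test_condition_at_background_floors_to_zero(self):
        assert nk.normalize_snv_frequencies(0.0026, 0.02, 0.0026) == 0.0

    def test_reference_below_background_is_error(self):
        with pytest.raises(NormalizationError):
            nk.normalize_snv_frequencies(0.01, 0.002, 0.0026)

    def test_coverage_formula(self):
        assert nk.coverage(CoverageInputs(120_000, 268, 480)) == pytest.approx(67_000)
        assert nk.coverage(CoverageInputs(1, 1, 1)) == 1
        with pytest.raises(ValueError):
            CoverageInputs(0, 268, 480)

    def test_fold_change(self):
        assert nk.fold_change(0.42, 0.022) == pytest.approx(19.09, abs=0.01)
        with pytest.raises(ValueError):
            nk.fold_change(1.0, 0.0)
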