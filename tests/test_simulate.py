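"""Ground-truth generator: event draws, sequence edits, read rendering."""

import numpy as np
import pytest
from scipy import stats

import nickseq as nk
from nickseq.simulate import (
    ReadPair,
    SimulationConfig,
    _trunc_geom,
    check_geometry,
    render_reads,
)


def trunc_geom_mean(q, cap):
    """Oracle: mean of P(k) proportional to q**k on 0..cap, by direct summation."""
    w = [q**k for k in range(cap + 1)]
    z = sum(w)
    return sum(k * w[k] for k in range(cap + 1)) / z


def joint_extent_means(q5, cap5, q3, cap3):
    """Oracle: E[L5], E[L3] of independent truncated geometrics conditioned on
    L5 + L3 >= 1, by exhaustive summation over the joint support."""
    w5 = [q5**k for k in range(cap5 + 1)]
    w3 = [q3**k for k in range(cap3 + 1)]
    z = m5 = m3 = 0.0
    for a, wa in enumerate(w5):
        for b, wb in enumerate(w3):
            if a + b == 0:
                continue
            p = wa * wb
            z += p
            m5 += a * p
            m3 += b * p
    return m5 / z, m3 / z


class TestDrawEvent:
    def test_p_mut_zero_always_unedited(self, site, amplicon, rng):
        cfg = SimulationConfig(p_mut=0.0)
        assert all(
            nk.draw_event(cfg, site, rng, amplicon).kind == "none" for _ in range(100)
        )

    def test_plus_one_g_insertion_creates_tgg_at_cut(self, site, amplicon, rng):
        cfg = SimulationConfig(
            p_mut=1.0, class_mix={"deletion": 0, "insertion": 1, "snv": 0, "donor_hdr": 0}
        )
        ev = nk.draw_event(cfg, site, rng, amplicon)
        edited = nk.apply_event(amplicon.sequence, ev)
        # ...T|G... becomes ...TGG... with the +1G at the nick bond
        assert edited[site.cut - 1 : site.cut + 2] == "TGG"

    def test_deletion_extent_means_match_truncated_geometric_oracle(
        self, site, amplicon
    ):
        rng = np.random.default_rng(7)
        cfg = SimulationConfig(
            p_mut=1.0,
            class_mix={"deletion": 1, "insertion": 0, "snv": 0, "donor_hdr": 0},
            p_del_1bp=0.0,
            q_del_5=0.5,
            q_del_3=0.5,
        )
        n = 10_000
        l5s, l3s = [], []
        for _ in range(n):
            ev = nk.draw_event(cfg, site, rng, amplicon)
            l5s.append(site.cut - ev.start)
            l3s.append(ev.start + ev.length - site.cut)
        e5, e3 = joint_extent_means(0.5, 10, 0.5, 25)
        for obs, exp in ((np.mean(l5s), e5), (np.mean(l3s), e3)):
            se = np.std(l5s if exp == e5 else l3s, ddof=1) / np.sqrt(n)
            assert abs(obs - exp) < 3 * se

    def test_forced_1bp_deletion_sits_at_cut(self, site, amplicon, rng):
        cfg = SimulationConfig(
            p_mut=1.0,
            class_mix={"deletion": 1, "insertion": 0, "snv": 0, "donor_hdr": 0},
            p_del_1bp=1.0,
        )
        ev = nk.draw_event(cfg, site, rng, amplicon)
        assert (ev.start, ev.length) == (site.cut, 1)

    def test_snv_zone_and_transversion_extremes(self, site, amplicon, rng):
        for tf in (0.0, 1.0):
            cfg = SimulationConfig(
                p_mut=1.0,
                class_mix={"deletion": 0, "insertion": 0, "snv": 1, "donor_hdr": 0},
                transversion_fraction=tf,
            )
            for _ in range(50):
                ev = nk.draw_event(cfg, site, rng, amplicon)
                assert site.cut - 10 <= ev.start < site.cut + 25
                purines = set("AG")
                is_tv = (ev.ref_base in purines) != (ev.alt_base in purines)
                assert is_tv == bool(tf)

    def test_zone_exceeding_amplicon_is_config_error(self, amplicon, rng):
        edge_site = nk.TargetSite("A" * 20, "AGG", "top", cut=5)
        with pytest.raises(ValueError):
            nk.draw_event(SimulationConfig(), edge_site, rng, amplicon)

    def test_class_mix_chi_square(self, site, amplicon):
        rng = np.random.default_rng(99)
        cfg = SimulationConfig(p_mut=1.0)
        counts = {"deletion": 0, "insertion": 0, "snv": 0}
        n = 10_000
        for _ in range(n):
            counts[nk.draw_event(cfg, site, rng, amplicon).kind] += 1
        expected = [cfg.class_mix[k] * n for k in counts]
        _, p = stats.chisquare(list(counts.values()), expected)
        assert p > 0.01


class TestApplyEvent:
    def test_identity(self):
        assert nk.apply_event("ACGTGC", nk.TrueEvent(kind="none")) == "ACGTGC"

    def test_deletion(self):
        ev = nk.TrueEvent(kind="deletion", start=2, length=2)
        assert nk.apply_event("ACGTGC", ev) == "ACGC"

    def test_insertion_and_snv_bookkeeping(self):
        ins = nk.TrueEvent(kind="insertion", start=3, inserted="TT")
        assert nk.apply_event("ACGTGC", ins) == "ACGTTTGC"
        snv = nk.TrueEvent(kind="snv", start=0, ref_base="A", alt_base="C")
        assert nk.apply_event("ACGTGC", snv) == "CCGTGC"

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            nk.apply_event("ACGT", nk.TrueEvent(kind="deletion", start=3, length=5))


class TestSimulateLibrary:
    def test_all_unedited_when_p_mut_zero(self, amplicon, site, rng):
        recs = nk.simulate_library(SimulationConfig(n_molecules=100, p_mut=0.0),
                                   amplicon, site, rng)
        assert len(recs) == 100
        assert all(r.event.kind == "none" for r in recs)
        assert all(r.derived_sequence == amplicon.sequence for r in recs)

    def test_mutant_count_in_exact_binomial_interval(self, amplicon, site):
        rng = np.random.default_rng(11)
        recs = nk.simulate_library(SimulationConfig(n_molecules=10_000, p_mut=0.022),
                                   amplicon, site, rng)
        mutants = sum(r.event.kind != "none" for r in recs)
        lo, hi = stats.binom.ppf([0.005, 0.995], 10_000, 0.022)
        assert lo <= mutants <= hi

    def test_umi_pairs_unique_at_expected_collision_rate(self, amplicon, site):
        # birthday bound over 4**20 keys: ~n^2/2 / 4^20 < 1e-3 expected collisions
        rng = np.random.default_rng(13)
        recs = nk.simulate_library(SimulationConfig(n_molecules=10_000, p_mut=0.0),
                                   amplicon, site, rng)
        keys = {(r.umi_a, r.umi_b) for r in recs}
        assert len(keys) == len(recs)

    def test_alphabet_closed_under_simulation(self, amplicon, site, rng):
        recs = nk.simulate_library(SimulationConfig(n_molecules=200, p_mut=0.5),
                                   amplicon, site, rng)
        pairs = render_reads(recs, SimulationConfig(e_seq=0.01), rng)
        assert all(set(r.derived_sequence) <= set("ACGT") for r in recs)
        assert all(set(p.seq1 + p.seq2) <= set("ACGT") for p in pairs)


class TestRenderReads:
    def test_noiseless_reads_reconstruct_molecules(self, amplicon, site, rng):
        cfg = SimulationConfig(n_molecules=20, p_mut=0.5, e_seq=0.0,
                               family_size_mean=1.0)
        recs = nk.simulate_library(cfg, amplicon, site, rng)
        pairs = render_reads(recs, cfg, rng)
        assert len(pairs) == len(recs)
        body = cfg.read_len - cfg.umi_len
        for rec, p in zip(recs, pairs):
            assert p.seq1 == rec.umi_a + rec.derived_sequence[:body]
            assert p.seq2 == rec.umi_b + nk.revcomp(rec.derived_sequence)[:body]

    def test_sequencing_error_rate_matches_binomial_expectation(self, amplicon, site):
        rng = np.random.default_rng(17)
        cfg = SimulationConfig(n_molecules=10_000, p_mut=0.0, e_seq=0.001,
                               family_size_mean=1.0)
        recs = nk.simulate_library(cfg, amplicon, site, rng)
        pairs = render_reads(recs, cfg, rng)
        body = cfg.read_len - cfg.umi_len
        mism = [
            sum(a != b for a, b in zip(p.seq1, rec.umi_a + rec.derived_sequence[:body]))
            for rec, p in zip(recs, pairs)
        ]
        n, L, e = len(mism), cfg.read_len, 0.001
        exp, se = L * e, np.sqrt(L * e * (1 - e) / n)
        assert abs(np.mean(mism) - exp) < 3 * se

    def test_same_seed_is_byte_identical(self, amplicon, site):
        def one():
            cfg = SimulationConfig(n_molecules=50, e_seq=0.01)
            rng = np.random.default_rng(23)
            recs = nk.simulate_library(cfg, amplicon, site, rng)
            return render_reads(recs, cfg, rng)

        assert one() == one()

    def test_family_sizes_min_one(self, amplicon, site, rng):
        cfg = SimulationConfig(n_molecules=100, family_size_mean=1.0)
        recs = nk.simulate_library(cfg, amplicon, site, rng)
        pairs = render_reads(recs, cfg, rng)
        assert len(pairs) == 100  # mean 1 => exactly one read per molecule

    def test_read_len_must_exceed_umi(self, amplicon, site, rng):
        cfg = SimulationConfig(n_molecules=1, read_len=10, umi_len=10)
        recs = nk.simulate_library(cfg, amplicon, site, rng)
        with pytest.raises(ValueError):
            render_reads(recs, cfg, rng)


class TestConfigValidation:
    def test_class_mix_must_sum_to_one(self):
        with pytest.raises(ValueError):
            SimulationConfig(class_mix={"deletion": 0.5, "insertion": 0.2, "snv": 0.2,
                                        "donor_hdr": 0.0})

    def test_donor_class_requires_donor_edit(self):
        with pytest.raises(ValueError):
            SimulationConfig(class_mix={"deletion": 0.5, "insertion": 0.2, "snv": 0.2,
                                        "donor_hdr": 0.1})

    def test_geometry_check_rejects_uncovered_window(self, amplicon):
        w = nk.ScoringWindow(0, 65)  # leftmost window cannot sit in the mate overlap
        with pytest.raises(ValueError):
            check_geometry(SimulationConfig(), amplicon, w, 22, 21)

    def test_geometry_check_accepts_default_window(self, amplicon, window):
        check_geometry(SimulationConfig(), amplicon, window, 22, 21)


def test_trunc_geom_marginal_matches_direct_summation():
    rng = np.random.default_rng(5)
    draws = [_trunc_geom(rng, 0.5, 10) for _ in range(20_000)]
    exp = trunc_geom_mean(0.5, 10)
    se = np.std(draws, ddof=1) / np.sqrt(len(draws))
    assert abs(np.mean(draws) - exp) < 3 * se
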