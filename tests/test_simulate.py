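import numpy as np
import pytest

from tetracross import (
    BivalentOutcome,
    ConfigurationError,
    CrossoverEvent,
    GeneticMap,
    PathwayParams,
    assign_chromatids,
    classify_interval,
    classify_table,
    count_intervals,
    derive_tetrad,
    draw_class1_positions,
    draw_class2_positions,
    enforce_obligate,
    get_preset,
    score_chiasmata,
    simulate_bivalent,
    simulate_experiment,
    simulate_tetrads,
)
from tetracross.simulate import _class1_flat, _class2_flat

from conftest import enumerate_tetrad_types


def make_outcome(gmap, positions, pairs):
    events = tuple(
        CrossoverEvent(p, "I", pair) for p, pair in zip(positions, pairs)
    )
    return BivalentOutcome(gmap, events)


class TestEventProcesses:
    def test_zero_intensity_always_empty(self, marker_map, rng):
        p = PathwayParams(class1_intensity=0.0, class2_intensity=0.0, obligate_co=False)
        for _ in range(20):
            assert draw_class1_positions(marker_map, p, rng) == []
            assert draw_class2_positions(marker_map, p, rng) == []

    def test_class2_counts_are_poisson(self, marker_map, rng):
        """Mean and variance of the class II count both equal lambda*L."""
        lam, L = 0.02, marker_map.length
        mi, _ = _class2_flat(L, lam, 100_000, rng)
        counts = np.bincount(mi, minlength=100_000)
        expected = lam * L
        se_mean = np.sqrt(expected / counts.size)
        assert counts.mean() == pytest.approx(expected, abs=4 * se_mean)
        assert counts.var() == pytest.approx(expected, rel=0.05)

    def test_shape_one_renewal_matches_poisson_moments(self, marker_map, rng):
        lam, L = 0.02, marker_map.length
        mi, _ = _class1_flat(L, lam, 1.0, 100_000, rng)
        counts = np.bincount(mi, minlength=100_000)
        expected = lam * L
        assert counts.mean() == pytest.approx(expected, rel=0.03)
        assert counts.var() == pytest.approx(expected, rel=0.05)

    def test_interference_underdisperses_counts(self, rng):
        """Gamma shape 10 gives variance-to-mean ratio well below 1."""
        mi, _ = _class1_flat(100.0, 0.02, 10.0, 100_000, rng)
        counts = np.bincount(mi, minlength=100_000)
        vmr = counts.var() / counts.mean()
        # At 1e5 draws the VMR standard error is ~0.005: clearly < 1
        assert vmr < 0.9

    def test_stationarity_translation_invariance(self, rng):
        """Equilibrium start: equal expected counts in congruent windows."""
        mi, pos = _class1_flat(110.0, 0.017, 5.0, 200_000, rng)
        early = ((pos >= 5) & (pos < 25)).sum() / 200_000
        late = ((pos >= 80) & (pos < 100)).sum() / 200_000
        expected = 0.017 * 20
        assert early == pytest.approx(expected, rel=0.03)
        assert late == pytest.approx(expected, rel=0.03)

    def test_disjoint_poisson_windows_uncorrelated(self, rng):
        mi, pos = _class2_flat(110.0, 0.02, 100_000, rng)
        n = 100_000
        a = np.bincount(mi[(pos >= 0) & (pos < 40)], minlength=n)
        b = np.bincount(mi[(pos >= 60) & (pos < 100)], minlength=n)
        r = np.corrcoef(a, b)[0, 1]
        assert abs(r) < 0.02


class TestObligate:
    def test_accepted_outcome_never_empty(self, rng):
        draw = lambda: list(rng.uniform(0, 1, rng.poisson(0.1)))
        for _ in range(200):
            events, _ = enforce_obligate(draw, rng)
            assert len(events) >= 1

    def test_rejection_rate_matches_closed_form(self, rng):
        """Acceptance prob for Poisson(0.1) draws is 1 - exp(-0.1)."""
        lam = 0.1
        draw = lambda: list(rng.uniform(0, 1, rng.poisson(lam)))
        rejections = [enforce_obligate(draw, rng)[1] for _ in range(4000)]
        p_accept = 1.0 - np.exp(-lam)
        expected_rej = (1 - p_accept) / p_accept
        se = np.sqrt((1 - p_accept) / p_accept**2 / 4000)
        assert np.mean(rejections) == pytest.approx(expected_rej, abs=4 * se)

    def test_empty_fraction_without_obligate(self, marker_map, rng):
        """With obligate off, empty-bivalent fraction is exp(-lambda*L)."""
        p = PathwayParams(class1_intensity=0.0, class2_intensity=0.01, obligate_co=False)
        empty = sum(
            not simulate_bivalent(marker_map, p, rng).events for _ in range(3000)
        )
        expected = np.exp(-0.01 * marker_map.length)
        se = np.sqrt(expected * (1 - expected) / 3000)
        assert empty / 3000 == pytest.approx(expected, abs=4 * se)

    def test_impossible_obligate_raises(self, marker_map, rng):
        p = PathwayParams(class1_intensity=0.0, class2_intensity=0.0, obligate_co=True)
        with pytest.raises(ConfigurationError):
            simulate_bivalent(marker_map, p, rng)


class TestTetradDerivation:
    def test_no_events_gives_parental_ditype(self, marker_map):
        rec = derive_tetrad(make_outcome(marker_map, [], []))
        assert sorted(rec.spores) == [(0, 0, 0), (0, 0, 0), (1, 1, 1), (1, 1, 1)]
        assert rec.qc == "ok"

    def test_single_event_hand_trace(self, marker_map):
        """One crossover between R and Y on pair (0,0): spores 100, 011, 111, 000."""
        rec = derive_tetrad(make_outcome(marker_map, [70.0], [(0, 0)]))
        assert sorted(rec.spores) == [(0, 0, 0), (0, 1, 1), (1, 0, 0), (1, 1, 1)]

    def test_double_exchange_same_strands_restores_parental(self, marker_map):
        """Two crossovers between the same physical strands cancel out.

        The first event swaps chromatids 0 and 2 (pair (0, 0) from the
        parental state); after it, the same physical pair is addressed by
        pair (1, 0) since strand origins have flipped.
        """
        rec = derive_tetrad(make_outcome(marker_map, [65.0, 75.0], [(0, 0), (1, 0)]))
        assert classify_interval(rec, 0, 1) == "PD"
        assert sorted(rec.spores) == [(0, 0, 0), (0, 0, 0), (1, 1, 1), (1, 1, 1)]

    def test_unsorted_events_rejected(self, marker_map):
        with pytest.raises(ValueError):
            make_outcome(marker_map, [75.0, 65.0], [(0, 0), (0, 0)])
        with pytest.raises(ValueError):
            assign_chromatids([(75.0, "I"), (65.0, "II")], np.random.default_rng(0))

    def test_every_tetrad_segregates_two_to_two(self, marker_map, rng):
        p = PathwayParams(obligate_co=False)
        for _ in range(300):
            rec = derive_tetrad(simulate_bivalent(marker_map, p, rng))
            for j in range(3):
                assert sum(s[j] for s in rec.spores) == 2

    @pytest.mark.parametrize("k", [0, 1, 2, 3])
    def test_fixed_event_count_matches_enumeration(self, marker_map, rng, k):
        """Simulated type frequencies for k interval COs match the 4^k oracle."""
        oracle = enumerate_tetrad_types(k)
        positions = list(np.linspace(62.0, 80.0, k))
        n = 8000
        counts = {"PD": 0, "TT": 0, "NPD": 0}
        for _ in range(n):
            events = assign_chromatids([(p, "I") for p in positions], rng)
            rec = derive_tetrad(BivalentOutcome(marker_map, tuple(events)))
            counts[classify_interval(rec, 0, 1)] += 1
        for t in counts:
            se = np.sqrt(max(oracle[t] * (1 - oracle[t]), 1e-9) / n)
            assert counts[t] / n == pytest.approx(oracle[t], abs=max(5 * se, 1e-9))


class TestChiasmaScoring:
    def test_three_events_one_arm_is_rod(self, marker_map):
        out = make_outcome(marker_map, [50.0, 60.0, 70.0], [(0, 0)] * 3)
        score = score_chiasmata(out)
        assert score.count == 1 and not score.univalent_pair

    def test_events_both_arms_is_ring(self, marker_map):
        out = make_outcome(marker_map, [10.0, 70.0], [(0, 0)] * 2)
        assert score_chiasmata(out).count == 2

    def test_no_events_is_univalent_pair(self, marker_map):
        score = score_chiasmata(make_outcome(marker_map, [], []))
        assert score.count == 0 and score.univalent_pair


class TestExperiment:
    def test_spo11_preset_no_chiasmata_all_univalents(self, wildtype_params):
        from tetracross import default_genome

        _, cyto = simulate_experiment(
            default_genome(), wildtype_params, get_preset("spo11"), 100, seed=1
        )
        assert (cyto["chiasmata"] == 0).all()
        assert (cyto["univalents"] == 10).all()

    def test_same_seed_identical_outputs(self, wildtype_params):
        from tetracross import default_genome

        g = default_genome()
        t1, c1 = simulate_experiment(g, wildtype_params, get_preset("wild_type"), 200, 42)
        t2, c2 = simulate_experiment(g, wildtype_params, get_preset("wild_type"), 200, 42)
        assert t1.equals(t2) and c1.equals(c2)

    def test_chiasma_cap_and_univalent_bookkeeping(self, wildtype_params):
        from tetracross import default_genome

        p = PathwayParams(obligate_co=False)
        _, cyto = simulate_experiment(default_genome(), p, get_preset("hei10"), 500, 7)
        assert cyto["chiasmata"].between(0, 10).all()
        assert cyto["univalents"].between(0, 10).all()
        # univalents come in pairs; a cell's chiasmata fit on its bivalents
        assert (cyto["univalents"] % 2 == 0).all()
        n_bivalents = 5 - cyto["univalents"] // 2
        assert (cyto["chiasmata"] <= 2 * n_bivalents).all()
        assert (cyto["chiasmata"] >= (cyto["univalents"] == 0)).any()

    def test_obligate_mode_eliminates_univalents(self, wildtype_params):
        from tetracross import default_genome

        _, cyto = simulate_experiment(
            default_genome(), wildtype_params, get_preset("wild_type"), 500, 11
        )
        assert (cyto["univalents"] == 0).all()
        assert (cyto["chiasmata"] >= 5).all()  # obligate: every bivalent scores >= 1

    def test_empty_genome_rejected(self, wildtype_params):
        with pytest.raises(ConfigurationError):
            simulate_experiment([], wildtype_params, get_preset("wild_type"), 10, 1)


class TestBatchEngine:
    def test_batch_matches_per_bivalent_frequencies(self, marker_map, rng):
        """The vectorised and object paths give the same tetrad-type law."""
        p = PathwayParams(class1_intensity=0.01, interference_shape=3.0,
                          class2_intensity=0.01, obligate_co=False)
        n = 6000
        table = simulate_tetrads(marker_map, p, n, rng)
        batch = count_intervals(table, "R", "Y")
        ref = {"PD": 0, "TT": 0, "NPD": 0}
        for _ in range(n):
            rec = derive_tetrad(simulate_bivalent(marker_map, p, rng))
            ref[classify_interval(rec, 0, 1)] += 1
        for t in ("PD", "TT", "NPD"):
            f_batch = getattr(batch, t) / n
            f_ref = ref[t] / n
            se = np.sqrt(max(f_ref * (1 - f_ref), 1e-9) / n) * np.sqrt(2)
            assert f_batch == pytest.approx(f_ref, abs=max(5 * se, 0.002))

    def test_batch_segregation_invariant(self, marker_map, rng):
        p = PathwayParams(obligate_co=False)
        table = simulate_tetrads(marker_map, p, 2000, rng)
        for m in ("R", "Y", "C"):
            total = sum(table[f"s{i}_{m}"] for i in range(1, 5))
            assert (total == 2).all()
        assert (classify_table(table, "R", "Y") != "excluded").all()
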