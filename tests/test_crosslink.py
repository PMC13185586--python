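import numpy as np
import pytest

from exposeq.crosslink import (
    TransitionSegment,
    TransitionTable,
    correlate_signals,
    ks_compare,
    threshold_signals,
    transition_rates,
    vparcl_signal,
)
from exposeq.pileup import CoverageBlock, build_pileup
from exposeq.reference import GenomeReference

from oracles import brute_ks_statistic


@pytest.fixture(scope="module")
def reference():
    gen = np.random.default_rng(71)
    return GenomeReference.random({"S": 300}, gen)


def _table(rates, masked=None, min_depth=1000, condition="CL-"):
    rates = np.asarray(rates, float)
    depth = np.full(len(rates), 2000)
    seg = TransitionSegment(
        positions=np.arange(1, len(rates) + 1),
        depth=depth,
        c_count=np.round(rates * depth).astype(int),
        masked=np.zeros(len(rates), bool) if masked is None else np.asarray(masked),
    )
    return TransitionTable({"S": seg}, condition=condition, min_depth=min_depth)


class TestTransitionRates:
    def test_toy_rate(self, reference):
        seq = reference.sequence("S")
        t_pos = seq.index("T", 50) + 1
        blocks = [CoverageBlock("S", t_pos - 5, t_pos + 5)] * 7 + [
            CoverageBlock("S", t_pos - 5, t_pos + 5, ((t_pos, "C"),))
        ] * 3
        pile = build_pileup(blocks, reference)
        table = transition_rates(pile, reference, min_depth=1, condition="CL+")
        seg = table.segments["S"]
        idx = list(seg.positions).index(t_pos)
        assert seg.depth[idx] == 10
        assert seg.rate[idx] == pytest.approx(0.3)

    def test_default_threshold_masks_depth_999(self, reference):
        seq = reference.sequence("S")
        t_pos = seq.index("T", 50) + 1
        blocks = [CoverageBlock("S", t_pos, t_pos)] * 999
        pile = build_pileup(blocks, reference)
        seg = transition_rates(pile, reference).segments["S"]
        idx = list(seg.positions).index(t_pos)
        assert bool(seg.masked[idx]) is True
        blocks.append(CoverageBlock("S", t_pos, t_pos))
        seg2 = transition_rates(build_pileup(blocks, reference), reference).segments["S"]
        assert bool(seg2.masked[idx]) is False

    def test_only_reference_t_positions(self, reference):
        pile = build_pileup([CoverageBlock("S", 1, 300)], reference)
        seg = transition_rates(pile, reference, min_depth=1).segments["S"]
        seq = reference.sequence("S")
        assert all(seq[p - 1] == "T" for p in seg.positions)
        assert len(seg.positions) == seq.count("T")

    def test_no_conversions_zero_rates(self, reference):
        pile = build_pileup([CoverageBlock("S", 1, 300)] * 5, reference)
        seg = transition_rates(pile, reference, min_depth=1).segments["S"]
        assert np.all(seg.rate[~seg.masked] == 0.0)

    def test_length_mismatch_is_hard_error(self, reference):
        other = GenomeReference.random({"S": 200}, np.random.default_rng(2))
        pile = build_pileup([CoverageBlock("S", 1, 200)], other)
        with pytest.raises(ValueError, match="length"):
            transition_rates(pile, reference)


class TestVparclSignal:
    def test_identical_rates_give_unity(self):
        track = vparcl_signal([_table([0.05] * 4, condition="CL+")],
                              [_table([0.05] * 4)])
        seg = track.segments["S"]
        assert np.allclose(seg.signal, 1.0, atol=0.05)

    def test_plain_ratio_with_zero_pseudo(self):
        track = vparcl_signal(
            [_table([0.3], condition="CL+")], [_table([0.1])], pseudo=0.0
        )
        assert track.segments["S"].signal[0] == pytest.approx(3.0)

    def test_zero_denominator_finite_with_pseudo(self):
        track = vparcl_signal(
            [_table([0.01], condition="CL+")], [_table([0.0])], pseudo=0.001
        )
        # independent arithmetic: (0.01 + 0.001) / (0 + 0.001) = 11.0
        assert track.segments["S"].signal[0] == pytest.approx(11.0)
        assert np.isfinite(track.segments["S"].signal[0])

    def test_default_pseudo_is_inverse_min_depth(self):
        track = vparcl_signal(
            [_table([0.1], condition="CL+")], [_table([0.1])]
        )
        assert track.pseudo == pytest.approx(1 / 1000)

    def test_mask_union_across_replicates(self):
        plus = [
            _table([0.1, 0.1], masked=[True, False], condition="CL+"),
            _table([0.1, 0.1], masked=[False, False], condition="CL+"),
        ]
        minus = [_table([0.1, 0.1], masked=[False, True])]
        track = vparcl_signal(plus, minus)
        assert list(track.segments["S"].masked) == [True, True]

    def test_replicate_averaging(self):
        plus = [_table([0.2], condition="CL+"), _table([0.4], condition="CL+")]
        minus = [_table([0.1]), _table([0.1])]
        track = vparcl_signal(plus, minus, pseudo=0.0)
        assert track.segments["S"].r_plus[0] == pytest.approx(0.3)
        assert track.segments["S"].signal[0] == pytest.approx(3.0)

    def test_all_masked_warns(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING):
            vparcl_signal(
                [_table([0.1], masked=[True], condition="CL+")],
                [_table([0.1], masked=[True])],
            )
        assert any("masked" in r.message for r in caplog.records)


class TestKsCompare:
    def test_identical_samples(self):
        res = ks_compare([0.1, 0.2, 0.3], [0.1, 0.2, 0.3])
        assert res.statistic == 0.0
        assert res.pvalue == pytest.approx(1.0)

    def test_disjoint_supports(self):
        res = ks_compare([0.1, 0.2], [0.9, 1.0])
        assert res.statistic == 1.0

    def test_matches_brute_force_ecdf_gap(self):
        gen = np.random.default_rng(5)
        for n in (10, 37, 100):
            x = gen.random(n)
            y = gen.random(n) ** 1.5
            res = ks_compare(x, y)
            assert res.statistic == pytest.approx(brute_ks_statistic(x, y), abs=1e-12)

    def test_exact_mode_small_samples(self):
        x = [0.1, 0.5, 0.9]
        y = [0.2, 0.6, 0.95]
        res = ks_compare(x, y)
        from scipy import stats

        ref = stats.ks_2samp(x, y, method="exact")
        assert res.pvalue == pytest.approx(ref.pvalue)

    def test_insufficient_positions(self):
        with pytest.raises(ValueError):
            ks_compare([0.1], [0.2, 0.3])


class TestCorrelateSignals:
    def test_self_correlation(self, rng):
        track = rng.random(50)
        res = correlate_signals(track, track)
        assert res.coefficient == pytest.approx(1.0)

    def test_negation_gives_minus_one(self, rng):
        track = rng.random(50)
        res = correlate_signals(track, -track)
        assert res.coefficient == pytest.approx(-1.0)

    def test_independent_noise_small(self):
        gen = np.random.default_rng(9)
        res = correlate_signals(gen.random(1000), gen.random(1000))
        assert abs(res.coefficient) < 0.1

    def test_constant_track_flagged_undefined(self):
        res = correlate_signals(np.ones(10), np.arange(10.0))
        assert res.undefined and res.coefficient is None

    def test_nan_positions_excluded(self):
        a = np.array([1.0, 2.0, np.nan, 4.0, 5.0])
        b = np.array([1.0, 2.0, 3.0, 4.0, np.nan])
        res = correlate_signals(a, b)
        assert res.n == 3
        assert res.coefficient == pytest.approx(1.0)

    def test_spearman_mode(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        b = np.exp(a)
        res = correlate_signals(a, b, method="spearman")
        assert res.coefficient == pytest.approx(1.0)


class TestThresholdSignals:
    def _track(self, signals):
        plus = _table(np.zeros(len(signals)), condition="CL+")
        minus = _table(np.zeros(len(signals)))
        track = vparcl_signal([plus], [minus])
        track.segments["S"].signal[:] = signals
        return track

    def test_no_signal_above_cutoff(self):
        res = threshold_signals(self._track([1.0, 1.0, 1.0]), 1.5)
        assert res.n_above == 0
        assert all(len(v) == 0 for v in res.positions.values())
        assert res.quantile_pct == 0.0
        assert res.percentile_pct == 100.0  # cutoff sits at the 100th percentile

    def test_counting_and_quantile(self):
        res = threshold_signals(self._track([1.0, 1.0, 1.0, 2.0]), 1.5)
        assert res.n_above == 1
        assert list(res.positions["S"]) == [4]
        assert res.quantile_pct == pytest.approx(25.0)

    def test_masked_positions_never_contribute(self):
        plus = _table([5.0, 5.0], masked=[True, False], condition="CL+")
        minus = _table([0.0, 0.0])
        track = vparcl_signal([plus], [minus])
        res = threshold_signals(track, 1.5)
        assert res.n_unmasked == 1
        assert list(res.positions["S"]) == [2]
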