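import numpy as np
import pandas as pd
import pytest

from ampcyto import (
    AmplificationQuantifier,
    BinningSpec,
    EventTable,
    SimulationTruth,
    concordance,
    define_bins,
    fold_and_snr,
    linearity_ratios,
    simulate_amplification_experiment,
    summarize_bins,
)


def _table(values, condition="c"):
    values = np.asarray(values, dtype=float)
    meta = pd.DataFrame({"condition_id": condition, "cycle_count": 1}, index=range(len(values)))
    return EventTable(values, ["reference", "ace"][: values.shape[1]], meta)


RAW_SPEC = BinningSpec(transformed_bins=False, min_bin_count=1)


class TestDefineBins:
    def test_equal_width_edges_and_max_in_last_bin(self):
        x = np.arange(11.0)
        t = _table(np.column_stack([x, x]))
        b = define_bins(t, RAW_SPEC)
        assert np.allclose(b.edges, np.arange(11.0))
        assert b.bin_ids[-1] == 10  # x = 10 (the max) belongs to bin 10

    def test_interior_edge_is_left_closed(self):
        x = np.concatenate([np.arange(11.0), [3.0]])
        t = _table(np.column_stack([x, x]))
        b = define_bins(t, RAW_SPEC)
        assert b.bin_ids[-1] == 4  # value exactly on edge 3.0 -> bin 4

    def test_counts_match_brute_force_histogram(self, rng):
        x = rng.uniform(0, 50, 1000)
        t = _table(np.column_stack([x, x]))
        b = define_bins(t, RAW_SPEC)
        edges = b.edges
        for bin_id in range(1, 11):
            lo, hi = edges[bin_id - 1], edges[bin_id]
            if bin_id < 10:
                expected = np.sum((x >= lo) & (x < hi))
            else:
                expected = np.sum((x >= lo) & (x <= hi))
            assert np.sum(b.bin_ids == bin_id) == expected

    def test_partition_invariant(self, rng):
        x = rng.uniform(0, 9, 500)
        t = _table(np.column_stack([x, x]))
        b = define_bins(t, BinningSpec())
        assert np.sum([(b.bin_ids == k).sum() for k in range(1, 11)]) == 500

    def test_degenerate_channel_errors(self):
        t = _table(np.ones((20, 2)))
        with pytest.raises(ValueError, match="degenerate"):
            define_bins(t, RAW_SPEC)

    def test_empty_table_errors(self):
        t = EventTable(np.empty((0, 2)), ["reference", "ace"])
        with pytest.raises(ValueError, match="empty"):
            define_bins(t, RAW_SPEC)


class TestSummarizeBins:
    def test_constant_target_medians(self, rng):
        x = rng.uniform(0, 10, 200)
        t = _table(np.column_stack([x, np.full(200, 4.0)]))
        b = define_bins(t, RAW_SPEC)
        s = summarize_bins(t, b, "ace")
        occupied = s.table[~s.table.flagged]
        assert (occupied["median"] == 4.0).all()

    def test_odd_count_median(self):
        x = np.array([0.0, 5.0, 10.0])
        t = _table(np.column_stack([x, [1.0, 2.0, 9.0]]))
        spec = BinningSpec(n_bins=1, negative_bins=(1,), transformed_bins=False, min_bin_count=1)
        s = summarize_bins(t, define_bins(t, spec), "ace")
        assert s.table["median"].iloc[0] == 2.0

    def test_medians_match_sort_and_pick_oracle(self, rng):
        x = rng.uniform(0, 10, 500)
        y = rng.uniform(0, 100, 500)
        t = _table(np.column_stack([x, y]))
        b = define_bins(t, RAW_SPEC)
        s = summarize_bins(t, b, "ace")
        for bin_id in range(1, 11):
            yb = np.sort(y[b.bin_ids == bin_id])
            if yb.size == 0:
                continue
            n = yb.size
            expected = yb[n // 2] if n % 2 else 0.5 * (yb[n // 2 - 1] + yb[n // 2])
            row = s.table[(s.table.bin == bin_id)].iloc[0]
            assert row["median"] == pytest.approx(expected, abs=1e-12)

    def test_count_floor_flags_sparse_bins(self, rng):
        x = np.concatenate([np.zeros(50), [100.0] * 3])
        t = _table(np.column_stack([x, x]))
        spec = BinningSpec(transformed_bins=False, min_bin_count=10)
        s = summarize_bins(t, define_bins(t, spec), "ace")
        top = s.table[s.table.bin == 10].iloc[0]
        assert top.flagged and np.isnan(top["median"])

    def test_unknown_channel(self, rng):
        t = _table(np.column_stack([np.arange(20.0), np.arange(20.0)]))
        with pytest.raises(KeyError):
            summarize_bins(t, define_bins(t, RAW_SPEC), "nope")


class TestLinearityRatios:
    def _summary(self, medians_by_condition):
        rows = []
        for cond, meds in medians_by_condition.items():
            for b, m in enumerate(meds, start=1):
                rows.append(
                    {"condition_id": cond, "bin": b, "count": 100, "median": m, "flagged": False}
                )
        from ampcyto.amplification import BinSummary

        return BinSummary(
            edges=np.arange(len(meds) + 1.0),
            table=pd.DataFrame(rows),
            negative_median={c: meds[0] for c, meds in medians_by_condition.items()},
            spec=BinningSpec(transformed_bins=False),
        )

    def test_equal_medians_all_ratios_one(self):
        s = self._summary({"c": [3.0] * 10})
        r = linearity_ratios(s)
        assert np.allclose(r.ratio_to_reference_bin, 1.0)

    def test_arithmetic_ladder(self):
        s = self._summary({"c": list(range(1, 11))})
        r = linearity_ratios(s)
        assert np.allclose(r.ratio_to_reference_bin, np.arange(1, 11) / 10.0)

    def test_reference_bin_ratio_exactly_one(self):
        s = self._summary({"c": [1.0, 2, 3, 4, 5, 6, 7, 8, 9, 7.77]})
        r = linearity_ratios(s)
        assert r[r.bin == 10].ratio_to_reference_bin.iloc[0] == 1.0

    def test_zero_reference_median_errors(self):
        s = self._summary({"c": [1.0] * 9 + [0.0]})
        with pytest.raises(ValueError, match="zero"):
            linearity_ratios(s)


class TestFoldAndSnr:
    def test_baseline_identity(self):
        truth = SimulationTruth(seed=13, n_cells=3000, cycle_gain={1: 1.0})
        tab = simulate_amplification_experiment(truth, [1])
        q = AmplificationQuantifier(baseline_condition="cycle_1").fit(tab)
        row = q.report_.iloc[0]
        assert row.fold_vs_baseline == 1.0 and row.snr_enhancement == 1.0

    def test_gain_13_recovered(self):
        truth = SimulationTruth(seed=14, n_cells=10_000, cycle_gain={1: 1.0, 500: 13.0})
        tab = simulate_amplification_experiment(truth)
        q = AmplificationQuantifier(baseline_condition="cycle_1").fit(tab)
        fold = q.report_.set_index("condition_id").fold_vs_baseline["cycle_500"]
        assert fold == pytest.approx(13.0, rel=0.10)

    def test_amplified_negatives_leave_snr_flat(self, rng):
        # counterexample: when noise is amplified as much as signal, SNR
        # enhancement stays ~1 despite a large fold
        n = 6000
        ref = np.concatenate([rng.uniform(0, 2, n // 2), rng.uniform(10, 100, n // 2)])
        base_ace = np.where(ref < 5, 2.0, ref)
        rows = []
        vals = []
        for cond, gain in (("base", 1.0), ("amp", 10.0)):
            vals.append(np.column_stack([ref, base_ace * gain]))
            rows.append(pd.DataFrame({"condition_id": cond}, index=range(n)))
        tab = EventTable(np.vstack(vals), ["reference", "ace"], pd.concat(rows, ignore_index=True))
        q = AmplificationQuantifier(
            baseline_condition="base", transformed_bins=False, min_bin_count=1
        ).fit(tab)
        rep = q.report_.set_index("condition_id")
        assert rep.fold_vs_baseline["amp"] == pytest.approx(10.0, rel=0.01)
        assert rep.snr_enhancement["amp"] == pytest.approx(1.0, rel=0.01)

    def test_missing_baseline_errors(self):
        truth = SimulationTruth(seed=15, n_cells=2000, cycle_gain={1: 1.0})
        tab = simulate_amplification_experiment(truth, [1])
        with pytest.raises(ValueError, match="zz"):
            AmplificationQuantifier(baseline_condition="zz").fit(tab)


class TestLinearityUnderGain:
    def test_ratio_profiles_drift_below_tolerance(self):
        truth = SimulationTruth(seed=16, n_cells=10_000, cycle_gain={1: 1.0, 500: 13.0})
        tab = simulate_amplification_experiment(truth)
        q = AmplificationQuantifier(baseline_condition="cycle_1").fit(tab)
        prof = q.ratios_.pivot(
            index="bin", columns="condition_id", values="ratio_to_reference_bin"
        )
        drift = (prof["cycle_1"] - prof["cycle_500"]).abs().max()
        assert drift < 0.05


class TestConcordance:
    def test_perfect_linear(self):
        x = np.linspace(0, 100, 50)
        t = _table(np.column_stack([x, 2 * x + 1]))
        # transformed correlation of an affine relation is close to, not
        # exactly, 1; raw-space check uses the underlying formula instead
        r = concordance(t, "reference", "ace")
        assert r > 0.99

    def test_matches_textbook_formula(self, rng):
        x = rng.uniform(0, 100, 300)
        y = rng.uniform(0, 100, 300)
        t = _table(np.column_stack([x, y]))
        xt, yt = np.arcsinh(x / 5), np.arcsinh(y / 5)
        num = np.sum((xt - xt.mean()) * (yt - yt.mean()))
        den = np.sqrt(np.sum((xt - xt.mean()) ** 2) * np.sum((yt - yt.mean()) ** 2))
        assert concordance(t, "reference", "ace") == pytest.approx(num / den, abs=1e-12)

    def test_constant_channel_errors(self):
        t = _table(np.column_stack([np.ones(10), np.arange(10.0)]))
        with pytest.raises(ValueError, match="constant"):
            concordance(t, "reference", "ace")


class TestEstimatorContract:
    def test_get_set_params_roundtrip(self):
        q = AmplificationQuantifier(n_bins=8)
        q2 = AmplificationQuantifier(**q.get_params())
        assert q2.n_bins == 8
        q2.set_params(n_bins=12)
        assert q2.get_params()["n_bins"] == 12
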