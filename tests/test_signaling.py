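import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from ampcyto import (
    EventTable,
    bp_r2,
    build_network,
    score_timecourse,
    sign_pseudotime,
    trajectory_stats,
)


def bp_r2_oracle(x, y, n_bins=10, min_bin_count=20):
    """Explicit-loop two-pass reference implementation."""
    order = sorted(range(len(x)), key=lambda i: (x[i], i))
    bins = [list(a) for a in np.array_split(order, n_bins)]
    bins = [b for b in bins if len(b) >= min_bin_count]
    kept = [i for b in bins for i in b]
    ybar = sum(y[i] for i in kept) / len(kept)
    ss_tot = sum((y[i] - ybar) ** 2 for i in kept)
    ss_res = 0.0
    for b in bins:
        m = sum(y[i] for i in b) / len(b)
        for i in b:
            ss_res += (y[i] - m) ** 2
    return max(0.0, 1.0 - ss_res / ss_tot)


class TestBpR2:
    def test_matches_oracle_on_random_instances(self, rng):
        for _ in range(25):
            n = int(rng.integers(200, 1000))
            x = rng.normal(size=n)
            y = rng.normal(size=n) + x * rng.uniform(0, 2)
            assert bp_r2(x, y) == pytest.approx(bp_r2_oracle(x, y), abs=1e-12)

    def test_identity_on_uniform_grid_is_near_one(self):
        x = np.linspace(0, 1, 1000)
        assert bp_r2(x, x) >= 0.98  # only within-bin grid variance remains

    def test_independent_null_is_small(self, rng):
        x, y = rng.normal(size=5000), rng.normal(size=5000)
        assert bp_r2(x, y) < 0.05

    @given(
        data=hnp.arrays(
            float, (300, 2),
            elements=st.floats(-50, 50, allow_nan=False, width=32),
        ),
        a=st.floats(0.1, 10),
        b=st.floats(-5, 5),
    )
    @settings(max_examples=30, derandomize=True, deadline=None)
    def test_invariance_monotone_x_affine_y(self, data, a, b):
        x, y = data[:, 0], data[:, 1]
        if np.ptp(y) == 0:
            return
        base = bp_r2(x, y, n_bins=5, min_bin_count=5)
        # strictly monotone transform of x (rank-preserving) leaves bins unchanged
        assert bp_r2(np.exp(x / 50.0), y, 5, 5) == pytest.approx(base, abs=1e-9)
        assert bp_r2(x, a * y + b, 5, 5) == pytest.approx(base, abs=1e-9)

    def test_constant_y_errors(self):
        with pytest.raises(ValueError, match="constant"):
            bp_r2(np.arange(300.0), np.ones(300))

    def test_too_few_events_errors(self):
        with pytest.raises(ValueError, match="at least"):
            bp_r2(np.arange(50.0), np.arange(50.0))  # < 10 bins * 20

    def test_negative_raw_score_clipped_to_zero(self, rng):
        x = rng.normal(size=400)
        y = rng.normal(size=400)
        s = bp_r2(x, y, n_bins=4, min_bin_count=10)
        assert 0.0 <= s <= 1.0


class TestScoreTimecourse:
    def test_summaries_are_sum_and_mean(self, coupled_timecourse):
        res = score_timecourse(coupled_timecourse, ["m1", "m2", "m3"])
        assert len(res.timepoints) == 8
        for _, row in res.summary.iterrows():
            pair_scores = res.scores[
                (res.scores.marker_x == row.marker_x) & (res.scores.marker_y == row.marker_y)
            ].score
            assert row.cumulative_sum == pytest.approx(pair_scores.sum())
            assert row["mean"] == pytest.approx(row.cumulative_sum / 8)

    def test_coupled_pair_strong_uncoupled_weak(self, coupled_timecourse):
        res = score_timecourse(coupled_timecourse, ["m1", "m2", "m3"])
        summ = res.summary.set_index(["marker_x", "marker_y"])["mean"]
        assert summ[("m1", "m2")] > 0.775
        assert summ[("m1", "m3")] < 0.05
        assert summ[("m3", "m2")] < 0.05

    def test_missing_timepoint_named(self, coupled_timecourse):
        with pytest.raises(ValueError, match="99"):
            score_timecourse(coupled_timecourse, ["m1", "m2"], timepoints=[0.0, 99.0])


class TestBuildNetwork:
    def _result(self, means, timepoints=8):
        rows = []
        for (a, b), m in means.items():
            rows.append(
                {"marker_x": a, "marker_y": b, "cumulative_sum": m * timepoints, "mean": m}
            )
            rows.append(
                {"marker_x": b, "marker_y": a, "cumulative_sum": m * timepoints, "mean": m}
            )
        from ampcyto.signaling import Bpr2Result

        return Bpr2Result(
            scores=pd.DataFrame(),
            summary=pd.DataFrame(rows),
            n_bins=10,
            min_bin_count=20,
            timepoints=tuple(float(t) for t in range(timepoints)),
        )

    def test_all_zero_means_empty_network(self):
        res = self._result({("a", "b"): 0.0, ("a", "c"): 0.0, ("b", "c"): 0.0})
        assert build_network(res).n_edges == 0

    def test_mean_and_sum_rules_equivalent(self, coupled_timecourse):
        res = score_timecourse(coupled_timecourse, ["m1", "m2", "m3"])
        by_mean = build_network(res, rule="mean", threshold=0.775)
        by_sum = build_network(res, rule="sum", threshold=6.2)
        assert [(a, b) for a, b, _ in by_mean.edges] == [(a, b) for a, b, _ in by_sum.edges]
        for (_, _, sm), (_, _, ss) in zip(by_mean.edges, by_sum.edges):
            assert ss == pytest.approx(8 * sm)

    def test_edge_strength_is_max_of_directions(self):
        from ampcyto.signaling import Bpr2Result

        summary = pd.DataFrame(
            [
                {"marker_x": "a", "marker_y": "b", "cumulative_sum": 6.4, "mean": 0.80},
                {"marker_x": "b", "marker_y": "a", "cumulative_sum": 6.0, "mean": 0.75},
            ]
        )
        res = Bpr2Result(pd.DataFrame(), summary, 10, 20, tuple(map(float, range(8))))
        net = build_network(res, rule="mean", threshold=0.775)
        assert net.edges == [("a", "b", 0.80)]

    def test_symmetric_under_marker_order(self, coupled_timecourse):
        res1 = score_timecourse(coupled_timecourse, ["m1", "m2", "m3"])
        res2 = score_timecourse(coupled_timecourse, ["m3", "m2", "m1"])
        e1 = build_network(res1).edges
        e2 = build_network(res2).edges
        assert [(a, b) for a, b, _ in e1] == [(a, b) for a, b, _ in e2]

    def test_unknown_rule(self):
        res = self._result({("a", "b"): 0.5})
        with pytest.raises(ValueError, match="rule"):
            build_network(res, rule="median")


class TestTrajectoryStats:
    def _one_condition(self, values_by_tp):
        vals, meta = [], []
        for t, v in values_by_tp.items():
            v = np.asarray(v, dtype=float)
            vals.append(v[:, None])
            meta.append(
                pd.DataFrame({"condition_id": "c", "timepoint_min": t}, index=range(v.size))
            )
        return EventTable(np.vstack(vals), ["m"], pd.concat(meta, ignore_index=True))

    def test_constant_values(self):
        t = self._one_condition({0.0: [5, 5, 5], 5.0: [5, 5, 5]})
        df = trajectory_stats(t, ["m"])
        assert (df.mean_signal == 5.0).all() and (df.cv == 0.0).all()

    def test_hand_computed_population_cv(self):
        t = self._one_condition({0.0: [2, 4, 4, 4, 5, 5, 7, 9], 5.0: [1, 1]})
        df = trajectory_stats(t, ["m"])
        row = df[df.timepoint_min == 0.0].iloc[0]
        assert row.mean_signal == 5.0 and row.cv == pytest.approx(0.4)

    def test_zero_mean_cv_flagged(self):
        t = self._one_condition({0.0: [0, 0], 5.0: [1, 1]})
        df = trajectory_stats(t, ["m"])
        row = df[df.timepoint_min == 0.0].iloc[0]
        assert not row.cv_defined and np.isnan(row.cv)

    def test_normalized_mean_endpoints(self):
        t = self._one_condition({0.0: [1, 1], 5.0: [3, 3], 10.0: [9, 9]})
        df = trajectory_stats(t, ["m"]).sort_values("timepoint_min")
        assert list(df.normalized_mean)[0] == 0.0
        assert list(df.normalized_mean)[-1] == 1.0

    def test_cv_drops_at_stimulated_timepoints(self, coupled_timecourse):
        df = trajectory_stats(coupled_timecourse, ["m1"])
        cv0 = df[df.timepoint_min == 0.0].cv.iloc[0]
        peak_tp = df.loc[df.mean_signal.idxmax(), "timepoint_min"]
        cv_peak = df[df.timepoint_min == peak_tp].cv.iloc[0]
        assert cv_peak < cv0


class TestSignPseudotime:
    def test_all_negative_phase(self):
        pt = np.array([0.1, 0.5, 1.0])
        out = sign_pseudotime(pt, np.array(["e"] * 3), "e")
        assert np.array_equal(out, -pt)

    def test_no_matching_phase_warns_identity(self):
        pt = np.array([0.2, 0.8])
        with pytest.warns(UserWarning, match="no cells"):
            out = sign_pseudotime(pt, np.array(["m", "m"]), "e")
        assert np.array_equal(out, pt)

    def test_mixed_elementwise(self, rng):
        pt = rng.uniform(0, 1, 200)
        labels = rng.choice(["EMT", "MET"], 200)
        out = sign_pseudotime(pt, labels, "EMT")
        assert np.allclose(np.abs(out), pt)
        assert np.all((out < 0) == ((labels == "EMT") & (pt > 0)))

    def test_rank_order_preserved_within_phase(self, rng):
        pt = np.sort(rng.uniform(0, 1, 50))
        labels = np.array(["EMT"] * 50)
        out = sign_pseudotime(pt, labels, "EMT")
        # negation reverses the axis but preserves within-phase ordering
        assert np.all(np.diff(out) <= 0)

    def test_out_of_range_pseudotime_rejected(self):
        with pytest.raises(ValueError, match="0, 1"):
            sign_pseudotime([1.5], ["e"], "e")
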