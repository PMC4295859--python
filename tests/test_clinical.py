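"""Plasma-panel statistics: exact-enumeration oracles for the signed-rank
and rank-sum tests, summaries, and correlation recovery."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import rankdata

from dosetrend import (
    PlasmaDesign,
    PlasmaPanel,
    correlate_markers,
    correlation_track,
    generate_plasma_panel,
    group_compare,
    paired_signed_rank,
    summarize_timecourse,
)
from dosetrend.clinical import PanelError


def signed_rank_oracle(diffs):
    """Exhaustive sign-flip enumeration of the two-sided signed-rank p."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    r = rankdata(np.abs(d))
    obs = r[d > 0].sum()
    mid = r.sum() / 2
    n = len(d)
    masks = (np.arange(2**n)[:, None] >> np.arange(n)) & 1
    sums = masks @ r
    return np.mean(np.abs(sums - mid) >= abs(obs - mid) - 1e-12)


def small_panel(records, schedule=("t0", "t1"), metadata=None):
    return PlasmaPanel(
        data=pd.DataFrame(records),
        metadata=metadata if metadata is not None else pd.DataFrame(),
        schedule=schedule,
    )


class TestPairedSignedRank:
    def test_six_concordant_pairs(self):
        w, p = paired_signed_rank([1, 2, 3, 4, 5, 6], [2, 3, 4, 5, 6, 7])
        assert w == 21.0
        assert p == pytest.approx(2 / 64)

    def test_symmetric_differences_give_p_one(self):
        w, p = paired_signed_rank([0, 0, 0, 0], [3, -3, 1, -1])
        assert p == 1.0

    def test_all_zero_differences_rejected(self):
        with pytest.raises(PanelError):
            paired_signed_rank([1, 2, 3], [1, 2, 3])

    @settings(max_examples=100, deadline=None)
    @given(st.lists(st.integers(-9, 9).filter(lambda v: v != 0), min_size=1, max_size=12))
    def test_matches_enumeration_oracle(self, diffs):
        base = np.zeros(len(diffs))
        w, p = paired_signed_rank(base, np.asarray(diffs, dtype=float))
        assert p == pytest.approx(signed_rank_oracle(diffs), abs=1e-12)

    def test_large_n_uses_consistent_approximation(self, rng):
        d = rng.normal(0.3, 1.0, 60)
        d = d[d != 0]
        _, p = paired_signed_rank(np.zeros(len(d)), d)
        from scipy.stats import wilcoxon

        assert p == pytest.approx(wilcoxon(d, method="approx", correction=False).pvalue)


class TestGroupCompare:
    @staticmethod
    def panel_with_groups(values_a, values_b):
        recs = []
        meta = []
        for i, v in enumerate(list(values_a) + list(values_b)):
            pid = f"P{i}"
            recs.append({"patient_id": pid, "timepoint": "t0", "marker": "M", "value": v})
            meta.append({"patient_id": pid,
                         "igcccg_group": "good" if i < len(values_a) else "poor"})
        return small_panel(recs, metadata=pd.DataFrame(meta))

    def test_fully_separated_groups_exact_p(self):
        panel = self.panel_with_groups([1, 2, 3], [4, 5, 6])
        u, p, summaries = group_compare(panel, "M", "t0", "igcccg_group")
        assert u == 0.0
        assert p == pytest.approx(0.1)
        assert summaries["good"] == "2.0 (1.0-3.0; n = 3)"

    def test_identical_groups_near_one(self):
        panel = self.panel_with_groups([1, 2, 3], [1, 2, 3])
        _, p, _ = group_compare(panel, "M", "t0", "igcccg_group")
        assert p > 0.9

    def test_matches_rank_arrangement_enumeration(self, rng):
        """Random small groups against an exhaustive arrangement oracle."""
        import itertools

        from scipy.stats import mannwhitneyu

        for _ in range(30):
            na, nb = rng.integers(2, 6), rng.integers(2, 6)
            # tie-free (continuous) samples: the exact arrangement null is
            # defined over untied ranks
            a = np.round(rng.random(na) * 30, 6)
            b = np.round(rng.random(nb) * 30, 6)
            panel = self.panel_with_groups(a, b)
            u_obs, p_obs, _ = group_compare(panel, "M", "t0", "igcccg_group")
            pooled = np.concatenate([a, b])
            n = len(pooled)
            u_null = []
            for idx in itertools.combinations(range(n), int(na)):
                mask = np.zeros(n, dtype=bool)
                mask[list(idx)] = True
                u_null.append(mannwhitneyu(pooled[mask], pooled[~mask],
                                           alternative="two-sided").statistic)
            u_null = np.asarray(u_null, dtype=float)
            mid = na * nb / 2
            p_exact = np.mean(np.abs(u_null - mid) >= abs(u_obs - mid) - 1e-12)
            assert p_obs == pytest.approx(p_exact, abs=0.02)

    def test_empty_group_rejected(self):
        panel = self.panel_with_groups([1, 2, 3], [])
        with pytest.raises(PanelError):
            group_compare(panel, "M", "t0", "igcccg_group")


class TestSummaries:
    def test_course_multiplier_shapes_the_median(self):
        design = PlasmaDesign(n_patients=41, seed=8)
        panel, truth = generate_plasma_panel(design)
        summary = summarize_timecourse(panel, "GDF-15")
        summary = summary.set_index("timepoint")
        base = summary.loc["c1d1", "median"]
        ratio = summary.loc["c1d8", "median"] / base
        assert ratio == pytest.approx(9.0, rel=0.5)  # strong day-8 spike
        assert summary.loc["c1d8", "p_vs_baseline"] < 0.01
        assert (summary["min"] <= summary["median"]).all()
        assert (summary["median"] <= summary["max"]).all()

    def test_constant_patients_give_p_one(self):
        recs = [
            {"patient_id": f"P{i}", "timepoint": t, "marker": "M", "value": 5.0}
            for i in range(6) for t in ("t0", "t1")
        ]
        summary = small_panel(recs).set_index = summarize_timecourse(small_panel(recs), "M")
        assert summary.loc[summary["timepoint"] == "t1", "p_vs_baseline"].iloc[0] == 1.0

    def test_median_invariant_to_panel_duplication(self):
        panel, _ = generate_plasma_panel(PlasmaDesign(n_patients=20, seed=3))
        s1 = summarize_timecourse(panel, "vWF")
        doubled = panel.data.copy()
        doubled["patient_id"] = doubled["patient_id"] + "b"
        big = PlasmaPanel(data=pd.concat([panel.data, doubled], ignore_index=True),
                          metadata=panel.metadata, schedule=panel.schedule)
        s2 = summarize_timecourse(big, "vWF")
        assert (s2["n"] == 2 * s1["n"]).all()
        np.testing.assert_allclose(s2["median"], s1["median"])

    def test_single_patient_tests_skipped(self):
        recs = [{"patient_id": "P0", "timepoint": t, "marker": "M", "value": v}
                for t, v in (("t0", 1.0), ("t1", 2.0))]
        summary = summarize_timecourse(small_panel(recs), "M")
        assert np.isnan(summary.loc[summary["timepoint"] == "t1", "p_vs_baseline"]).all()


class TestCorrelations:
    @staticmethod
    def pairs_panel(xs, ys):
        recs = []
        for i, (x, y) in enumerate(zip(xs, ys)):
            recs.append({"patient_id": f"P{i}", "timepoint": "t0", "marker": "A", "value": x})
            recs.append({"patient_id": f"P{i}", "timepoint": "t0", "marker": "B", "value": y})
        return small_panel(recs, schedule=("t0",))

    def test_monotone_and_antimonotone(self):
        r, _, n = correlate_markers(self.pairs_panel([1, 2, 3, 4, 5], [2, 4, 8, 16, 32]),
                                    "A", "B", "t0")
        assert r == pytest.approx(1.0) and n == 5
        r, _, _ = correlate_markers(self.pairs_panel([1, 2, 3, 4, 5], [32, 16, 8, 4, 2]),
                                    "A", "B", "t0")
        assert r == pytest.approx(-1.0)

    def test_copula_target_recovered_at_large_n(self):
        panel, truth = generate_plasma_panel(
            PlasmaDesign(n_patients=400, cross_marker_rho=0.35, seed=6)
        )
        r, p, n = correlate_markers(panel, "GDF-15", "hsCRP", "c1d1")
        assert n == 400
        assert abs(r - 0.35) <= 0.1

    def test_too_few_pairs_rejected(self):
        with pytest.raises(PanelError):
            correlate_markers(self.pairs_panel([1, 2, 3], [1, 2, 3]), "A", "B", "t0")

    def test_track_covers_schedule(self):
        panel, _ = generate_plasma_panel(PlasmaDesign(n_patients=30, seed=4))
        track = correlation_track(panel, "GDF-15", "vWF")
        assert list(track["timepoint"]) == list(panel.schedule)
        assert (track["n"] == 30).all()
        assert "holm_p" in track.columns


class TestNullCalibration:
    def test_wilcoxon_rejects_at_nominal_rate_under_null(self, rng):
        """Flat multipliers, independent markers: paired test vs baseline
        rejects at about the nominal 5% level."""
        flat = {m: {} for m in ("GDF-15", "vWF", "hsCRP")}
        rejections = 0
        n_reps = 400
        for rep in range(n_reps):
            panel, _ = generate_plasma_panel(
                PlasmaDesign(n_patients=20, timepoint_labels=("c1d1", "c1d8"),
                             course_multipliers=flat, cross_marker_rho=0.0,
                             seed=50_000 + rep)
            )
            wide = panel.pivot("GDF-15")
            _, p = paired_signed_rank(wide["c1d1"], wide["c1d8"])
            rejections += p <= 0.05
        rate = rejections / n_reps
        assert 0.02 <= rate <= 0.08
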