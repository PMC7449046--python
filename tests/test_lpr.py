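"""LPR computation, summaries and the SSR multiple range test."""

import dataclasses
import itertools

import numpy as np
import pandas as pd
import pytest

from lprseg.lpr import (
    LPRRecord,
    compute_lpr,
    comparison_frame,
    records_to_frame,
    ssr_test,
    summarize,
)
from lprseg.synthetic import ClassMask, SceneConfig, generate_scene


def make_records(groups, seed=0):
    """Simulated records: {label: (mean, sd, n)}."""
    r = np.random.default_rng(seed)
    records = []
    for label, (mean, sd, n) in groups.items():
        for i, v in enumerate(r.normal(mean, sd, n)):
            records.append(LPRRecord(f"{label}_{i}", L=1, P=1, lpr=float(v),
                                     background_count=0,
                                     metadata={"group": label}))
    return records


class TestComputeLPR:
    def test_direct_division(self):
        labels = np.zeros((20, 20), np.int64)
        labels.ravel()[:300] = 1
        labels.ravel()[300:400] = 2
        rec = compute_lpr(ClassMask(labels), image_id="x")
        assert rec.L == 300 and rec.P == 100
        assert rec.lpr == pytest.approx(3.0)
        assert rec.L + rec.P + rec.background_count == 400

    def test_all_background_undefined(self):
        rec = compute_lpr(np.zeros((8, 8), np.int64))
        assert rec.L == 0 and rec.P == 0
        assert not rec.defined

    def test_strict_mode_raises_on_no_panicle(self):
        with pytest.raises(ZeroDivisionError):
            compute_lpr(np.zeros((8, 8), np.int64), strict=True)

    def test_generator_bookkeeping_is_reproduced_exactly(self):
        cfg = SceneConfig(height=160, width=160, seed=21)
        _, mask = generate_scene(cfg)
        counts = mask.class_counts()
        rec = compute_lpr(mask)
        assert rec.L == counts[1]
        assert rec.P == counts[2]
        assert rec.lpr == pytest.approx(counts[1] / counts[2])

    def test_pixel_permutation_invariance(self, rng):
        labels = rng.integers(0, 3, (12, 12))
        shuffled = rng.permutation(labels.ravel()).reshape(12, 12)
        a, b = compute_lpr(labels), compute_lpr(shuffled)
        assert (a.L, a.P) == (b.L, b.P)

    def test_scale_invariance_under_upscaling(self, rng):
        labels = rng.integers(0, 3, (16, 16))
        up = labels.repeat(2, axis=0).repeat(2, axis=1)
        a, b = compute_lpr(labels), compute_lpr(up)
        assert b.L == 4 * a.L and b.P == 4 * a.P
        assert b.lpr == pytest.approx(a.lpr)

    def test_monotone_in_leaf_pixels(self, rng):
        labels = rng.integers(1, 3, (10, 10))
        labels[0, :5] = 0
        rec = compute_lpr(labels)
        more = labels.copy()
        more[0, :5] = 1  # background -> leaf
        assert compute_lpr(more).lpr > rec.lpr


class TestSummarize:
    def test_single_record(self):
        out = summarize(make_records({"a": (2.0, 0.0, 1)}), "group")
        assert out.loc[0, "mean"] == pytest.approx(2.0)
        assert np.isnan(out.loc[0, "sd"])

    def test_constant_groups(self):
        recs = make_records({"lo": (2.0, 0.0, 5), "hi": (4.0, 0.0, 5)})
        out = summarize(recs, "group").set_index("group")
        assert out.loc["lo", "mean"] == pytest.approx(2.0)
        assert out.loc["hi", "mean"] == pytest.approx(4.0)
        assert out.loc["lo", "sd"] == pytest.approx(0.0)

    def test_undefined_records_excluded(self):
        recs = make_records({"a": (2.0, 0.1, 4)})
        recs.append(LPRRecord("und", L=5, P=0, lpr=float("nan"),
                              background_count=0, metadata={"group": "a"}))
        out = summarize(recs, "group")
        assert out.loc[0, "n"] == 4

    def test_all_undefined_signals(self):
        recs = [LPRRecord("u", 0, 0, float("nan"), 0, {"group": "a"})]
        with pytest.raises(ValueError, match="undefined"):
            summarize(recs, "group")

    def test_group_means_recover_configured_ratios(self):
        """Scene area ratios set by the generator reappear in LPR means."""
        records = []
        for label, (n_leaves, n_panicles) in {
                "leafy": ((10, 14), (2, 3)), "grainy": ((3, 5), (5, 8))}.items():
            cfg = SceneConfig(height=128, width=128, n_leaves=n_leaves,
                              n_panicles=n_panicles)
            for i in range(12):
                _, mask = generate_scene(dataclasses.replace(cfg, seed=100 + i))
                records.append(compute_lpr(mask, image_id=f"{label}{i}",
                                           metadata={"group": label}))
        out = summarize(records, "group").set_index("group")
        assert out.loc["leafy", "mean"] > out.loc["grainy", "mean"]


class TestSSRTest:
    def test_identical_groups_share_letter(self):
        vals = np.array([2.0, 2.1, 1.9, 2.05])
        recs = []
        for g in ("a", "b", "c"):
            for i, v in enumerate(vals):
                recs.append(LPRRecord(f"{g}{i}", 1, 1, float(v), 0,
                                      {"group": g}))
        cmp_res = ssr_test(recs, "group")
        letters = set(cmp_res.letters.values())
        assert len(letters) == 1

    def test_well_separated_groups_distinct_letters(self):
        recs = make_records({"lo": (2.0, 0.1, 10), "hi": (5.0, 0.1, 10)},
                            seed=1)
        cmp_res = ssr_test(recs, "group", alpha=0.05)
        assert cmp_res.letters["lo"] != cmp_res.letters["hi"]
        assert ("hi", "lo") in cmp_res.significant_pairs

    def test_needs_two_groups_of_two(self):
        with pytest.raises(ValueError, match="2 groups"):
            ssr_test(make_records({"a": (2.0, 0.1, 5)}), "group")
        bad = make_records({"a": (2.0, 0.1, 5), "b": (3.0, 0.1, 1)})
        with pytest.raises(ValueError, match="fewer than 2"):
            ssr_test(bad, "group")

    def test_comparison_frame_sorted_descending(self):
        recs = make_records({"lo": (2.0, 0.1, 6), "mid": (3.0, 0.1, 6),
                             "hi": (5.0, 0.1, 6)}, seed=2)
        frame = comparison_frame(ssr_test(recs, "group"))
        assert list(frame["group"]) == ["hi", "mid", "lo"]
        assert (np.diff(frame["mean"]) <= 0).all()

    @staticmethod
    def perm_pvalue(a, b, n_perm=10_000, seed=0):
        r = np.random.default_rng(seed)
        obs = abs(a.mean() - b.mean())
        pooled = np.concatenate([a, b])
        count = 0
        for _ in range(n_perm):
            r.shuffle(pooled)
            d = abs(pooled[:len(a)].mean() - pooled[len(a):].mean())
            if d >= obs:
                count += 1
        return count / n_perm

    def test_agrees_with_permutation_oracle(self):
        """Pairwise declarations match a 10,000-permutation test
        qualitatively in clearly-separated and clearly-overlapping cases."""
        r = np.random.default_rng(3)
        base = np.random.default_rng(9).normal(3.0, 1.0, 8)
        overlapping = []
        for k, g in enumerate("abc"):
            for i, v in enumerate(base + 0.01 * k):  # tiny shifts of one draw
                overlapping.append(LPRRecord(f"{g}{i}", 1, 1, float(v), 0,
                                             {"group": g}))
        cases = {
            "separated": make_records({"a": (2.0, 0.1, 8), "b": (3.5, 0.1, 8),
                                       "c": (5.0, 0.1, 8)}, seed=4),
            "overlapping": overlapping,
        }
        for name, recs in cases.items():
            frame = records_to_frame(recs)
            cmp_res = ssr_test(recs, "group", alpha=0.05)
            for ga, gb in itertools.combinations("abc", 2):
                a = frame.loc[frame["group"] == ga, "lpr"].to_numpy()
                b = frame.loc[frame["group"] == gb, "lpr"].to_numpy()
                p = self.perm_pvalue(a, b)
                ssr_sig = ((ga, gb) in cmp_res.significant_pairs
                           or (gb, ga) in cmp_res.significant_pairs)
                if name == "separated":
                    assert p < 0.01 and ssr_sig
                else:
                    assert p > 0.2 and not ssr_sig


class TestDailyPattern:
    def test_u_shaped_leaf_visibility_recovered(self):
        """Morning/evening scenes show more leaf (low sun shades panicles);
        noon shows the most panicle.  The configured U-shape over five times
        of day must reappear in the ordering of LPR group means."""
        # leaf counts follow a U over the day; panicle counts stay fixed
        day_plan = {"05:55": (14, 18), "09:00": (9, 12), "12:00": (5, 7),
                    "15:00": (9, 12), "17:56": (14, 18)}
        records = []
        for k, (t, n_leaves) in enumerate(day_plan.items()):
            cfg = SceneConfig(height=96, width=96, n_leaves=n_leaves,
                              n_panicles=(3, 4))
            for i in range(10):
                _, mask = generate_scene(
                    dataclasses.replace(cfg, seed=1000 * k + i))
                records.append(compute_lpr(mask, image_id=f"{t}_{i}",
                                           metadata={"time": t}))
        means = summarize(records, "time").set_index("time")["mean"]
        assert means["05:55"] > means["09:00"] > means["12:00"]
        assert means["17:56"] > means["15:00"] > means["12:00"]
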