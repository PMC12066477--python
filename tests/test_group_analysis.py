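"""ANOVA, LSD post hoc, Spearman and percent change against brute-force oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from fvmap.group_analysis import (
    IOPDurationStudy,
    ZeroVarianceError,
    lsd_posthoc,
    one_way_anova,
    percent_change,
    spearman,
    study_report,
)


def _table(groups, side="experimental", cls="glial", arm="model"):
    rows = []
    for wk, values in groups.items():
        for i, v in enumerate(values):
            rows.append(
                {
                    "eye_id": f"w{wk}e{i}{side[:1]}",
                    "group": f"Gw{wk}",
                    "week": wk,
                    "side": side,
                    "arm": arm,
                    "tissue_class": cls,
                    "typical_pa": float(v),
                }
            )
    return pd.DataFrame(rows)


def brute_force_anova(groups):
    """Textbook sums-of-squares ANOVA, computed independently."""
    all_vals = [v for vals in groups.values() for v in vals]
    grand = sum(all_vals) / len(all_vals)
    ss_b = sum(len(v) * (sum(v) / len(v) - grand) ** 2 for v in groups.values())
    ss_w = sum(sum((x - sum(v) / len(v)) ** 2 for x in v) for v in groups.values())
    df_b = len(groups) - 1
    df_w = len(all_vals) - len(groups)
    return (ss_b / df_b) / (ss_w / df_w)


def brute_force_spearman(x, y):
    """Midrank Spearman computed from first principles."""

    def midranks(a):
        order = sorted(range(len(a)), key=lambda i: a[i])
        ranks = [0.0] * len(a)
        i = 0
        while i < len(a):
            j = i
            while j + 1 < len(a) and a[order[j + 1]] == a[order[i]]:
                j += 1
            r = (i + j) / 2 + 1
            for t in range(i, j + 1):
                ranks[order[t]] = r
            i = j + 1
        return ranks

    rx, ry = midranks(list(x)), midranks(list(y))
    mx, my = sum(rx) / len(rx), sum(ry) / len(ry)
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = (
        sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry)
    ) ** 0.5
    return num / den


class TestOneWayAnova:
    def test_identical_data_zero_variance(self):
        table = _table({0: [5.0] * 4, 4: [5.0] * 4})
        with pytest.raises(ZeroVarianceError, match="zero_variance"):
            one_way_anova(table)

    def test_two_groups_f_equals_t_squared(self, rng):
        a, b = rng.normal(10, 2, 8), rng.normal(12, 2, 6)
        table = _table({0: a, 4: b})
        res = one_way_anova(table)
        t, _ = stats.ttest_ind(a, b)
        assert res.f_statistic == pytest.approx(t**2, rel=1e-10)

    def test_textbook_dataset_matches_brute_force(self):
        groups = {
            0: [6.1, 5.9, 6.3, 6.0, 6.2],
            4: [5.0, 5.2, 4.8, 5.1, 4.9],
            8: [4.0, 4.3, 3.9, 4.1, 4.2],
        }
        res = one_way_anova(_table(groups))
        assert res.f_statistic == pytest.approx(brute_force_anova(groups), rel=1e-10)
        f_ref, p_ref = stats.f_oneway(*groups.values())
        assert res.f_statistic == pytest.approx(f_ref, rel=1e-10)
        assert res.p_value == pytest.approx(p_ref, rel=1e-10)
        assert res.df_between == 2
        assert res.df_within == 12

    def test_undersized_group_rejected(self):
        table = _table({0: [1.0, 2.0], 4: [3.0]})
        with pytest.raises(ValueError, match="4"):
            one_way_anova(table)


class TestLsdPosthoc:
    def test_equal_means_give_t_zero_p_one(self):
        table = _table({0: [5.0, 6.0, 7.0], 4: [5.0, 6.0, 7.0], 8: [1.0, 2.0, 3.0]})
        res = lsd_posthoc(one_way_anova(table))
        pair = next(p for p in res.pairs if {p[0], p[1]} == {0, 4})
        assert pair[3] == pytest.approx(0.0, abs=1e-12)
        assert pair[4] == pytest.approx(1.0, abs=1e-12)

    def test_two_group_lsd_equals_pooled_t_test(self, rng):
        a, b = rng.normal(10, 2, 7), rng.normal(13, 2, 5)
        table = _table({0: a, 4: b})
        res = lsd_posthoc(one_way_anova(table))
        t_ref, p_ref = stats.ttest_ind(a, b)
        assert res.pairs[0][3] == pytest.approx(t_ref, rel=1e-10)
        assert res.pairs[0][4] == pytest.approx(p_ref, rel=1e-10)

    def test_brute_force_t_all_pairs(self, rng):
        groups = {w: rng.normal(10 - w / 4, 1.5, 6) for w in (0, 4, 8, 12)}
        an = one_way_anova(_table(groups))
        res = lsd_posthoc(an)
        for a, b, diff, t, p, _sig in res.pairs:
            t_bf = (np.mean(groups[a]) - np.mean(groups[b])) / np.sqrt(
                an.mse_within * (1 / 6 + 1 / 6)
            )
            assert t == pytest.approx(t_bf, rel=1e-10)
            assert p == pytest.approx(2 * stats.t.sf(abs(t_bf), an.df_within), rel=1e-10)

    def test_shifted_group_detected(self, rng):
        """One group shifted by 3 SD: its three pairs are significant nearly
        always, while the three null pairs reject at roughly the nominal rate
        (LSD is uncorrected by design)."""
        n_power_hits = 0
        n_null_rejections = 0
        for seed in range(50):
            r = np.random.default_rng(seed)
            groups = {w: r.normal(10, 1, 6) for w in (0, 4, 8)}
            groups[12] = r.normal(13, 1, 6)  # shifted by 3*SD
            res = lsd_posthoc(one_way_anova(_table(groups)))
            sig = {frozenset((a, b)) for a, b, *_rest, s in [(p[0], p[1], p[5]) for p in res.pairs] if s}
            want = {frozenset((12, w)) for w in (0, 4, 8)}
            if want <= sig:
                n_power_hits += 1
            n_null_rejections += len(sig - want)
        assert n_power_hits >= 45  # >= 90% of runs detect all three shifted pairs
        # 150 null pairs at alpha 0.05: expect ~7.5 spurious rejections
        assert n_null_rejections <= 25


class TestSpearman:
    def test_perfect_monotone_decrease(self):
        table = _table({0: [10.0], 4: [8.0], 8: [6.0], 12: [4.0]})
        table.loc[:, "eye_id"] = [f"e{i}" for i in range(len(table))]
        res = spearman(table)
        assert res.r == pytest.approx(-1.0)

    def test_invariance_under_monotone_x_transform(self, rng):
        y = rng.normal(10, 2, 12)
        weeks = np.repeat([0, 4, 8, 12], 3)
        t1 = _table({w: y[weeks == w] for w in (0, 4, 8, 12)})
        r1 = spearman(t1).r
        t2 = t1.copy()
        t2["week"] = np.exp(t2["week"] / 4.0)  # strictly increasing transform
        r2 = spearman(t2).r
        assert r1 == pytest.approx(r2, rel=1e-12)

    def test_tied_data_matches_midrank_oracle(self):
        x = [0, 0, 4, 4, 8, 8, 12, 12]
        y = [9.0, 8.5, 8.5, 7.0, 7.0, 6.0, 5.5, 5.5]
        table = pd.DataFrame(
            {
                "eye_id": [f"e{i}" for i in range(8)],
                "group": "g",
                "week": x,
                "side": "experimental",
                "arm": "model",
                "tissue_class": "glial",
                "typical_pa": y,
            }
        )
        res = spearman(table)
        assert res.r == pytest.approx(brute_force_spearman(x, y), rel=1e-10)
        r_ref, p_ref = stats.spearmanr(x, y)
        assert res.r == pytest.approx(r_ref, rel=1e-12)
        assert res.p_value == pytest.approx(p_ref, rel=1e-12)

    def test_constant_variable_rejected(self):
        table = _table({4: [5.0, 5.0, 5.0]})
        with pytest.raises((ZeroVarianceError, ValueError)):
            spearman(table)


class TestPercentChange:
    def test_no_change_gives_zero(self):
        table = _table({0: [10.0, 10.0], 4: [10.0, 10.0]})
        out = percent_change(table, "glial")
        assert out[0].percent_decrease == pytest.approx(0.0)

    def test_arithmetic(self):
        table = _table({0: [3.10, 3.10], 4: [2.00, 2.00]})
        out = percent_change(table, "glial")
        assert out[0].percent_decrease == pytest.approx(100 * (1 - 2.00 / 3.10), abs=1e-9)
        assert out[0].percent_decrease == pytest.approx(35.48, abs=0.01)

    def test_missing_reference_rejected(self):
        table = _table({4: [2.0, 2.0], 8: [1.0, 1.0]})
        with pytest.raises(ValueError, match="reference"):
            percent_change(table, "glial")


class TestStudyReport:
    def _full_table(self, rng, effect=True):
        decl = {0: 1.0, 4: 0.645, 8: 0.258, 12: 0.194} if effect else {w: 1.0 for w in (0, 4, 8, 12)}
        frames = []
        for cls, base in (("glial", 14e3), ("axon", 4.7e3)):
            exp = {w: base * decl[w] * rng.lognormal(0, 0.1, 6) for w in (0, 4, 8, 12)}
            frames.append(_table(exp, side="experimental", cls=cls))
            contra = {w: base * rng.lognormal(0, 0.1, 6) for w in (4, 8, 12)}
            frames.append(_table(contra, side="contralateral", cls=cls))
        return pd.concat(frames, ignore_index=True)

    def test_report_structure_and_recovery(self, rng):
        table = self._full_table(rng)
        report = study_report(table)
        for cls in ("glial", "axon"):
            block = report["classes"][cls]
            assert block["experimental_anova"]["significant"]
            assert block["experimental_spearman"]["r"] < 0
            assert set(block["percent_decrease_vs_week0"]) == {"4", "8", "12"}
            assert "contralateral_anova" in block
            assert "contralateral_vs_week0_anova" in block

    def test_model_object_summary(self, rng):
        res = IOPDurationStudy(self._full_table(rng)).fit()
        text = res.summary()
        assert "Spearman" in text and "LSD" in text

    def test_contralateral_null_mostly_nonsignificant(self):
        n_nonsig = 0
        for seed in range(40):
            rng = np.random.default_rng(seed + 1000)
            table = self._full_table(rng, effect=False)
            rep = study_report(table)
            n_nonsig += not rep["classes"]["glial"]["contralateral_anova"]["significant"]
        assert n_nonsig >= 36  # nominal type-I behavior at alpha = 0.05

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError, match="missing columns"):
            IOPDurationStudy(pd.DataFrame({"week": [1]}))
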