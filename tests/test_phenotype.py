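"""Metabolic syndrome flags, Friedewald LDL, adjusted correlations, the 2-df
group association test, Wilcoxon rank-sum, cross-tabs and subgroup scans."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from gutnet import phenotype as ph
from gutnet.exceptions import GutnetError

from conftest import make_table


def panel(**kw):
    base = {
        "sex": "M", "tg": 100.0, "hdl": 55.0, "sbp": 115.0, "dbp": 75.0,
        "glucose": 90.0,
        "med_tg_lowering": False, "med_hdl_raising": False,
        "med_antihypertensive": False, "med_antidiabetic": False,
    }
    base.update(kw)
    return pd.DataFrame([base], index=["subj"])


class TestMetsFlags:
    @pytest.mark.parametrize(
        "kw, flag, expected",
        [
            (dict(sex="F", hdl=50.0), "hdl_flag", True),   # women: <=50
            (dict(sex="F", hdl=50.5), "hdl_flag", False),
            (dict(sex="M", hdl=45.0), "hdl_flag", False),  # men: <40
            (dict(sex="M", hdl=39.9), "hdl_flag", True),
            (dict(glucose=100.0), "glucose_flag", True),   # >=100
            (dict(glucose=99.9), "glucose_flag", False),
            (dict(tg=150.0), "tg_flag", False),            # strictly >150
            (dict(tg=150.1), "tg_flag", True),
            (dict(sbp=131.0), "bp_flag", True),
            (dict(dbp=86.0), "bp_flag", True),
            (dict(sbp=130.0, dbp=85.0), "bp_flag", False),
        ],
    )
    def test_threshold_conventions(self, kw, flag, expected):
        flags = ph.mets_flags(panel(**kw))
        assert bool(flags.loc["subj", flag]) is expected

    def test_medication_substitutes_for_value(self):
        flags = ph.mets_flags(panel(tg=np.nan, med_tg_lowering=True))
        assert bool(flags.loc["subj", "tg_flag"])

    def test_missing_value_without_med_is_undetermined(self):
        with pytest.warns(UserWarning, match="undetermined"):
            flags = ph.mets_flags(panel(tg=np.nan))
        assert pd.isna(flags.loc["subj", "tg_flag"])
        assert flags.loc["subj", "n_traits"] == 0

    def test_male_hdl_rule_configurable(self):
        strict = ph.mets_flags(panel(sex="M", hdl=40.0))
        loose = ph.mets_flags(panel(sex="M", hdl=40.0), hdl_male_rule="less-equal")
        assert not bool(strict.loc["subj", "hdl_flag"])
        assert bool(loose.loc["subj", "hdl_flag"])

    def test_any_trait_iff_count_positive(self):
        flags = ph.mets_flags(panel(tg=200.0, glucose=120.0))
        assert flags.loc["subj", "n_traits"] == 2
        assert bool(flags.loc["subj", "any_trait"])

    @given(
        tg=st.floats(50, 400), glucose=st.floats(60, 200),
        sbp=st.floats(90, 200), dbp=st.floats(50, 120),
        bump=st.floats(0.1, 50),
    )
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_risk_direction(self, tg, glucose, sbp, dbp, bump):
        lo = ph.mets_flags(panel(tg=tg, glucose=glucose, sbp=sbp, dbp=dbp))
        hi = ph.mets_flags(
            panel(tg=tg + bump, glucose=glucose + bump, sbp=sbp + bump,
                  dbp=dbp + bump)
        )
        for flag in ("tg_flag", "glucose_flag", "bp_flag"):
            assert bool(hi.loc["subj", flag]) >= bool(lo.loc["subj", flag])


class TestFriedewald:
    def test_standard_arithmetic(self):
        assert ph.friedewald_ldl(200, 50, 100) == pytest.approx(130.0)

    def test_degenerate_zero(self):
        assert ph.friedewald_ldl(50, 50, 0) == pytest.approx(0.0)

    def test_domain_edge_undefined(self):
        with pytest.warns(UserWarning):
            assert math.isnan(ph.friedewald_ldl(200, 50, 400))


class TestAdjustedCorrelation:
    def test_identity_with_constant_covariate_effect(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=50)
        cov = pd.DataFrame({"age": rng.normal(48, 10, 50)})
        r, p = ph.adjusted_correlation(x, x, cov)
        assert r == pytest.approx(1.0)
        assert p == 0.0

    def test_null_type_one_error_calibrated(self):
        rng = np.random.default_rng(7)
        n_rep, n, alpha = 1000, 310, 0.05
        cov_template = pd.DataFrame(
            {"age": rng.normal(48, 13, n), "sex": rng.integers(0, 2, n)}
        )
        rej = 0
        for _ in range(n_rep):
            x = rng.standard_normal(n)
            y = rng.standard_normal(n)
            _r, p = ph.adjusted_correlation(x, y, cov_template)
            rej += p <= alpha
        rate = rej / n_rep
        se = math.sqrt(alpha * (1 - alpha) / n_rep)
        assert abs(rate - alpha) < 3 * se

    def test_partial_correlation_recovery(self):
        rng = np.random.default_rng(3)
        n = 310
        age = rng.normal(48, 13, n)
        # x, y share a partial correlation of 0.3 given age
        common = rng.standard_normal(n)
        x = 0.5 * age + math.sqrt(0.3) * common + math.sqrt(0.7) * rng.standard_normal(n)
        y = -0.3 * age + math.sqrt(0.3) * common + math.sqrt(0.7) * rng.standard_normal(n)
        cov = pd.DataFrame({"age": age})
        r, _p = ph.adjusted_correlation(x, y, cov)
        assert r == pytest.approx(0.3, abs=0.1)

    def test_collinear_covariates_rejected(self):
        rng = np.random.default_rng(4)
        cov = pd.DataFrame({"a": np.ones(20), "b": 2 * np.ones(20)})
        with pytest.raises(GutnetError):
            ph.adjusted_correlation(rng.normal(size=20), rng.normal(size=20), cov)


class TestGroupAssociation:
    def _data(self, means, n_per=40, noise=1.0, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for g, mu in enumerate(means, start=1):
            for _ in range(n_per):
                age = rng.normal(48, 12)
                sex = rng.integers(0, 2)
                rows.append(
                    {"group": g, "age": age, "sex_male": float(sex),
                     "trait": mu + 0.1 * age + noise * rng.standard_normal()}
                )
        frame = pd.DataFrame(rows, index=[f"s{i}" for i in range(len(rows))])
        return frame

    def test_null_trait_not_flagged(self):
        frame = self._data([5.0, 5.0, 5.0], n_per=60, seed=1)
        res = ph.group_association(
            frame["trait"], frame["group"], frame[["age", "sex_male"]]
        )
        assert res.p_value > 0.01
        means = res.adjusted_means["mean"]
        assert means.max() - means.min() < 1.0

    def test_separated_group_isolated_by_contrast(self):
        frame = self._data([0.0, 0.0, 10.0], noise=0.1, seed=2)
        res = ph.group_association(
            frame["trait"], frame["group"], frame[["age", "sex_male"]]
        )
        assert res.p_value < 1e-6
        assert res.contrasts is not None
        p3 = res.contrasts.set_index("contrast").loc["3 vs rest", "p"]
        assert p3 < 1e-6

    def test_f_statistic_matches_sums_of_squares_oracle(self):
        frame = self._data([1.0, 2.0, 1.5], n_per=10, seed=3)  # 30 rows
        res = ph.group_association(
            frame["trait"], frame["group"], frame[["age", "sex_male"]]
        )
        # independent SSE decomposition via explicit projections
        y = frame["trait"].to_numpy()
        x_red = np.column_stack(
            [np.ones(30), frame["age"], frame["sex_male"]]
        )
        x_full = np.column_stack(
            [x_red, (frame["group"] == 2), (frame["group"] == 3)]
        ).astype(float)

        def sse(x):
            beta, *_ = np.linalg.lstsq(x, y, rcond=None)
            r = y - x @ beta
            return r @ r

        f = ((sse(x_red) - sse(x_full)) / 2) / (sse(x_full) / (30 - 5))
        p = stats.f.sf(f, 2, 25)
        assert res.p_value == pytest.approx(p, abs=1e-9)

    def test_reduces_to_oneway_anova_without_covariate_effect(self):
        rng = np.random.default_rng(5)
        y = np.concatenate([rng.normal(m, 1.0, 20) for m in (0.0, 0.5, 1.0)])
        frame = pd.DataFrame(
            {
                "trait": y,
                "group": np.repeat([1, 2, 3], 20),
                "zero": np.zeros(60) + rng.normal(0, 1e-12, 60),
            },
            index=[f"s{i}" for i in range(60)],
        )
        res = ph.group_association(frame["trait"], frame["group"], None)
        f_ref, p_ref = stats.f_oneway(y[:20], y[20:40], y[40:])
        assert res.p_value == pytest.approx(p_ref, rel=1e-9)

    def test_binary_trait_uses_logistic_lr(self):
        rng = np.random.default_rng(6)
        frame = self._data([0, 0, 0], n_per=50, seed=6)
        frame["flag"] = (
            rng.random(len(frame)) < np.where(frame["group"] == 3, 0.8, 0.2)
        ).astype(float)
        res = ph.group_association(
            frame["flag"], frame["group"], frame[["age", "sex_male"]], binary=True
        )
        assert res.kind == "logistic"
        assert res.p_value < 1e-4

    def test_tiny_group_rejected(self):
        frame = self._data([0, 0, 0], n_per=5)
        frame = frame[~((frame["group"] == 3) & (frame.index != frame.index[-1]))]
        with pytest.raises(GutnetError):
            ph.group_association(
                frame["trait"], frame["group"], frame[["age", "sex_male"]]
            )

    def test_null_type_one_error_calibrated(self):
        rng = np.random.default_rng(11)
        n_rep, alpha = 500, 0.05
        rej = 0
        for rep in range(n_rep):
            frame = self._data([1.0, 1.0, 1.0], n_per=30, seed=1000 + rep)
            res = ph.group_association(
                frame["trait"], frame["group"], frame[["age", "sex_male"]]
            )
            rej += res.p_value <= alpha
        rate = rej / n_rep
        se = math.sqrt(alpha * (1 - alpha) / n_rep)
        assert abs(rate - alpha) < 3 * se


class TestWilcoxon:
    def test_identical_samples(self):
        x = [1.5, 2.5, 3.5, 4.5]
        _w, p = ph.wilcoxon_rank_sum(x, x)
        assert p > 0.8

    def test_complete_separation_exact(self):
        x = list(range(10))
        y = list(range(100, 110))
        _w, p = ph.wilcoxon_rank_sum(x, y)
        assert p == pytest.approx(2 / math.comb(20, 10), rel=1e-9)

    def test_matches_exact_enumeration_oracle(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=6)
        y = rng.normal(0.8, 1, size=6)
        _w, p = ph.wilcoxon_rank_sum(x, y)
        # enumeration over all C(12,6) group assignments of the pooled data
        import itertools

        pooled = np.concatenate([x, y])
        ranks = stats.rankdata(pooled)
        obs = ranks[:6].sum()
        n_x = 6
        total = 0
        extreme = 0
        mean_w = ranks.sum() * n_x / 12
        for combo in itertools.combinations(range(12), n_x):
            w = ranks[list(combo)].sum()
            total += 1
            if abs(w - mean_w) >= abs(obs - mean_w) - 1e-12:
                extreme += 1
        assert p == pytest.approx(extreme / total, rel=1e-9)


class TestOccupationCrosstab:
    def _table4_men(self):
        # printed men's occupation-by-network counts
        rows = []
        counts = {
            "farmer": (29, 0, 15),
            "tradesman": (22, 5, 16),
            "teacher/shopkeeper": (12, 3, 4),
            "unknown/retired": (2, 2, 2),
        }
        i = 0
        for occ, per_net in counts.items():
            for net, n in zip((1, 2, 3), per_net):
                for _ in range(n):
                    rows.append({"id": f"m{i}", "sex": "M", "occupation": occ,
                                 "group": net})
                    i += 1
        frame = pd.DataFrame(rows).set_index("id")
        return frame

    def test_printed_counts_give_printed_percentage(self):
        frame = self._table4_men()
        out = ph.occupation_crosstab(frame["group"], frame)
        men = out["M"]
        assert men.loc["farmer", "network_1_n"] == 29
        assert men.loc["farmer", "network_1_pct"] == pytest.approx(44.6, abs=0.05)

    def test_column_percentages_sum_to_100(self):
        frame = self._table4_men()
        men = ph.occupation_crosstab(frame["group"], frame)["M"]
        for net in (1, 2, 3):
            assert men[f"network_{net}_pct"].sum() == pytest.approx(100.0, abs=0.1)

    def test_single_occupation_everything_100(self):
        frame = pd.DataFrame(
            {"sex": ["M"] * 6, "occupation": ["farmer"] * 6,
             "group": [1, 1, 2, 2, 3, 3]},
            index=[f"s{i}" for i in range(6)],
        )
        men = ph.occupation_crosstab(frame["group"], frame)["M"]
        for net in (1, 2, 3):
            assert men.loc["farmer", f"network_{net}_pct"] == pytest.approx(100.0)


class TestSubgroupCompare:
    def _cohort(self, seed=0, enriched=None):
        rng = np.random.default_rng(seed)
        n = 60
        counts = {}
        for i in range(8):
            lam = 50
            base = rng.poisson(lam, n) + 1
            counts[f"G{i}"] = base.tolist()
        if enriched:
            boosted = np.array(counts[enriched])
            boosted[: n // 2] *= 10
            counts[enriched] = boosted.tolist()
        return make_table(counts, samples=[f"S{j}" for j in range(n)])

    def test_null_subset_no_discoveries(self):
        table = self._cohort(seed=1)
        mask = [i < 30 for i in range(60)]
        res = ph.subgroup_abundance_compare(table, mask)
        assert (res["q"] > 0.05).all()

    def test_planted_enrichment_detected_with_right_sign(self):
        # closure drags every other taxon down, so the planted taxon is the
        # unique significantly *enriched* one
        table = self._cohort(seed=2, enriched="G3")
        mask = [i < 30 for i in range(60)]
        res = ph.subgroup_abundance_compare(table, mask).set_index("taxon")
        assert res.loc["G3", "q"] < 0.01
        assert res.loc["G3", "median_diff"] > 0
        others = res.drop(index="G3")
        assert (others["median_diff"] < 0).all()

    def test_empty_complement_rejected(self):
        table = self._cohort(seed=3)
        with pytest.raises(GutnetError):
            ph.subgroup_abundance_compare(table, [True] * 60)
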