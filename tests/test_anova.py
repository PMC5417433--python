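"""Transforms, ANOVA, protected LSD, compact letters and the outlier scan."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from pinebeetle.anova import (
    MONOTERPENES,
    TRANSFORM_REGISTRY,
    anova_from_summary,
    apply_transform,
    blocked_anova,
    bonferroni_outlier_scan,
    compact_letter_display,
    oneway_anova,
    protected_lsd,
    transform_for,
)


class TestTransforms:
    @pytest.mark.parametrize(
        "transform, x, expected",
        [("sqrt", 4.0, 2.0), ("log1p", 0.0, 0.0), ("log1p", 9.0, np.log(10.0)),
         ("identity", 3.7, 3.7)],
    )
    def test_elementwise_values(self, transform, x, expected):
        assert apply_transform([x], transform)[0] == pytest.approx(expected)

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            apply_transform([-1.0], "sqrt")

    def test_registry_covers_all_analytes(self):
        assert transform_for("trap_count") == "sqrt"
        assert transform_for("4-allylanisole") == "sqrt"
        assert transform_for("alpha-pinene") == "identity"
        for compound in set(MONOTERPENES) - {"alpha-pinene"}:
            assert transform_for(compound) == "log1p"
        assert set(MONOTERPENES) <= set(TRANSFORM_REGISTRY)


class TestOneWay:
    def test_hand_computed_example(self):
        res = oneway_anova({"A": [1, 2, 3], "B": [4, 5, 6]})
        assert res.F == pytest.approx(13.5)
        assert (res.df_num, res.df_den) == (1, 4)
        assert res.F == pytest.approx(res.ms_between / res.ms_within)

    def test_no_between_group_signal(self):
        res = oneway_anova({"A": [1, 2, 3], "B": [1, 2, 3]})
        assert res.F == pytest.approx(0.0, abs=1e-12)

    def test_zero_residual_df_raises(self):
        with pytest.raises(ValueError, match="residual"):
            oneway_anova({"A": [1], "B": [2]})

    @given(st.integers(0, 10_000))
    @settings(max_examples=50, deadline=None)
    def test_summary_reconstruction_is_exact_for_balanced_data(self, seed):
        rng = np.random.default_rng(seed)
        k = int(rng.integers(2, 6))
        n = int(rng.integers(2, 8))
        data = {f"g{i}": rng.normal(rng.normal(0, 2), 1, n) for i in range(k)}
        raw = oneway_anova(data)
        means = [v.mean() for v in data.values()]
        ses = [v.std(ddof=1) / np.sqrt(n) for v in data.values()]
        rec = anova_from_summary(means, ses, n)
        assert rec.F == pytest.approx(raw.F, rel=1e-10)
        assert (rec.df_num, rec.df_den) == (raw.df_num, raw.df_den)


class TestSummaryAnova:
    def test_all_means_equal_gives_zero_F(self):
        res = anova_from_summary([2.0, 2.0, 2.0], [0.1, 0.2, 0.3], 4)
        assert res.F == pytest.approx(0.0, abs=1e-12)

    def test_rejects_small_n(self):
        with pytest.raises(ValueError):
            anova_from_summary([1.0, 2.0], [0.1, 0.1], 1)


class TestBlockedAnova:
    @staticmethod
    def _rcb(rng, treat_effects, site_effects, week_effects, noise=1.0, reps=1):
        rows = []
        for s, se_ in enumerate(site_effects):
            for w, we in enumerate(week_effects):
                for t, te in enumerate(treat_effects):
                    for _ in range(reps):
                        rows.append({
                            "site": f"s{s}", "week": f"w{w}", "treatment": f"t{t}",
                            "count": te + se_ + we + noise * rng.standard_normal(),
                        })
        return pd.DataFrame(rows)

    def test_inert_blocks_reduce_to_oneway(self, rng):
        df = self._rcb(rng, [0, 1, 2], [0.0], [0.0], reps=5)
        blocked = blocked_anova(df, "count", "treatment", blocks=["site", "week"])
        oneway = oneway_anova({t: g["count"].to_numpy()
                               for t, g in df.groupby("treatment")})
        assert blocked.F == pytest.approx(oneway.F, rel=1e-9)

    def test_matches_normal_equations_oracle(self, rng):
        """Partial F for treatment equals a direct least-squares computation."""
        df = self._rcb(rng, [0, 2, 4, 1], [0, 1.5], [0, -1, 1])

        def rss(X, y):
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            return float(np.sum((y - X @ beta) ** 2))

        y = df["count"].to_numpy()
        X_blocks = np.column_stack(
            [np.ones(len(df))]
            + [(df["site"] == s).to_numpy(float) for s in sorted(df["site"].unique())[1:]]
            + [(df["week"] == w).to_numpy(float) for w in sorted(df["week"].unique())[1:]]
        )
        X_full = np.column_stack(
            [X_blocks]
            + [(df["treatment"] == t).to_numpy(float)
               for t in sorted(df["treatment"].unique())[1:]]
        )
        df_num = X_full.shape[1] - X_blocks.shape[1]
        df_den = len(df) - X_full.shape[1]
        F_oracle = ((rss(X_blocks, y) - rss(X_full, y)) / df_num) / (rss(X_full, y) / df_den)
        res = blocked_anova(df, "count", "treatment", blocks=["site", "week"])
        assert res.F == pytest.approx(F_oracle, rel=1e-9)
        assert (res.df_num, res.df_den) == (df_num, df_den)

    def test_invariant_to_block_relabeling(self, rng):
        df = self._rcb(rng, [0, 2, 4], [0, 1.5, -1], [0, 1])
        res1 = blocked_anova(df, "count", "treatment", blocks=["site", "week"])
        relabeled = df.assign(site=df["site"].map(lambda s: "zz" + s[::-1]))
        res2 = blocked_anova(relabeled, "count", "treatment", blocks=["site", "week"])
        assert res1.F == pytest.approx(res2.F, rel=1e-12)


class TestProtectedLSD:
    def test_significant_omnibus_separates_groups(self):
        groups = {"A": [1, 2, 3], "B": [4, 5, 6]}
        res = oneway_anova(groups)
        letters = protected_lsd(res, groups)
        # LSD = t(.975,4)*sqrt(1*(2/3)) ~ 2.27 < |mean diff| = 3
        assert letters.omnibus_significant
        assert set(letters.letters.values()) == {"a", "b"}

    def test_protection_blocks_pairwise_when_omnibus_ns(self):
        groups = {"A": [1.0, 2.0, 3.0], "B": [1.5, 2.5, 3.5], "C": [1.2, 2.2, 3.4]}
        res = oneway_anova(groups)
        assert res.p_value > 0.05
        letters = protected_lsd(res, groups)
        assert not letters.omnibus_significant
        assert letters.significant_pairs == ()
        assert set(letters.letters.values()) == {"a"}

    def test_chain_overlap_case(self):
        """A != C but A = B and B = C gives the classic a / ab / b pattern."""
        rng = np.random.default_rng(3)
        groups = {
            "A": 0.0 + rng.standard_normal(8),
            "B": 1.1 + rng.standard_normal(8),
            "C": 2.2 + rng.standard_normal(8),
        }
        res = oneway_anova(groups)
        letters = protected_lsd(res, groups)
        sig = set(map(frozenset, letters.significant_pairs))
        if sig == {frozenset({"C", "A"})}:  # the intended configuration
            assert letters.letters["C"] == "a"
            assert letters.letters["B"] == "ab"
            assert letters.letters["A"] == "b"

    def test_letter_sharing_iff_not_significant(self, rng):
        for _ in range(20):
            k = int(rng.integers(3, 6))
            groups = {f"g{i}": rng.normal(rng.normal(0, 1.5), 1, 6) for i in range(k)}
            letters = protected_lsd(oneway_anova(groups), groups)
            sig = set(map(frozenset, letters.significant_pairs))
            names = list(groups)
            for i, a in enumerate(names):
                for b in names[i + 1:]:
                    shared = set(letters.letters[a]) & set(letters.letters[b])
                    assert bool(shared) == (frozenset({a, b}) not in sig)


class TestCompactLetters:
    def test_no_significant_pairs(self):
        letters = compact_letter_display([], ["A", "B", "C"])
        assert letters == {"A": "a", "B": "a", "C": "a"}

    def test_all_pairs_significant(self):
        pairs = [("A", "B"), ("A", "C"), ("B", "C")]
        letters = compact_letter_display(pairs, ["A", "B", "C"])
        assert sorted(letters.values()) == ["a", "b", "c"]

    def test_chain_insert_absorb(self):
        letters = compact_letter_display([("A", "C")], ["A", "B", "C"])
        assert letters == {"A": "a", "B": "ab", "C": "b"}

    def test_accepts_symmetric_matrix(self):
        mat = pd.DataFrame(False, index=["A", "B"], columns=["A", "B"])
        mat.loc["A", "B"] = mat.loc["B", "A"] = True
        letters = compact_letter_display(mat, ["A", "B"])
        assert letters == {"A": "a", "B": "b"}

    def test_rejects_asymmetric_matrix(self):
        mat = pd.DataFrame(False, index=["A", "B"], columns=["A", "B"])
        mat.loc["A", "B"] = True
        with pytest.raises(ValueError, match="symmetric"):
            compact_letter_display(mat, ["A", "B"])


class TestOutlierScan:
    @staticmethod
    def _tame(rng, n=20):
        return pd.DataFrame({
            "treatment": ["a", "b"] * (n // 2),
            "count": rng.normal(10, 1, n).clip(min=0),
        })

    def test_gross_point_is_flagged(self, rng):
        df = self._tame(rng)
        df.loc[len(df)] = {"treatment": "a", "count": 10 + 10 * 1.0 * 10}  # ~10 SDs out
        report = bonferroni_outlier_scan(df, "count", "treatment",
                                         candidates=[len(df) - 1])
        assert report.flagged == (len(df) - 1,)
        assert report.threshold == pytest.approx(0.05 / len(df))
        assert report.p_values[len(df) - 1] < report.threshold

    def test_no_candidates_empty_report(self, rng):
        report = bonferroni_outlier_scan(self._tame(rng), "count", "treatment",
                                         candidates=[])
        assert report.flagged == ()
        assert report.p_values == {}

    def test_homogeneous_data_nothing_flagged(self, rng):
        df = self._tame(rng)
        report = bonferroni_outlier_scan(df, "count", "treatment",
                                         candidates=list(df.index))
        assert report.flagged == ()
        # oracle: max |studentized residual| is far below the Bonferroni cut
        assert min(report.p_values.values()) > report.threshold

    def test_threshold_uses_total_observation_count(self, rng):
        df = self._tame(rng, n=30)
        report = bonferroni_outlier_scan(df, "count", "treatment",
                                         candidates=[0, 1], alpha=0.05)
        assert report.n_total == 30
        assert report.threshold == pytest.approx(0.05 / 30)

    def test_unknown_candidate_raises(self, rng):
        with pytest.raises(ValueError, match="not in records"):
            bonferroni_outlier_scan(self._tame(rng), "count", "treatment",
                                    candidates=[999])
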