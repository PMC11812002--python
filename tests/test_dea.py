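import numpy as np
import pandas as pd
import pytest
from scipy import stats as ss

from quantdea.annotation import ContrastVector
from quantdea.dea import (
    STATUS_IMPUTED,
    STATUS_MODELLED,
    STATUS_NOT_ESTIMABLE,
    ModerationParams,
    adjust_fdr,
    fit_group_model,
    handle_missing_groups,
    moderate_variance,
    run_dea,
)
from quantdea.dea import test_contrast as evaluate_contrast
from quantdea.model import ColumnRoles, TidyQuantTable

from .conftest import make_annotation


def series(values: dict[str, float]) -> pd.Series:
    return pd.Series(values, dtype=float)


AB = make_annotation({"A": ["a1", "a2"], "B": ["b1", "b2"]}, control="A")


class TestFitGroupModel:
    def test_two_group_closed_form(self):
        fit = fit_group_model(series({"a1": 2, "a2": 2, "b1": 1, "b2": 1}), AB)
        assert fit.group_means == pytest.approx({"A": 2.0, "B": 1.0})
        assert fit.sigma2 == pytest.approx(0.0)
        assert fit.df_resid == 2

    def test_fully_unobserved_group_not_estimable(self):
        ann = make_annotation({"A": ["a1", "a2"], "B": ["b1", "b2"], "C": ["c1"]},
                              control="A")
        fit = fit_group_model(series({"a1": 2, "a2": 3, "b1": 1, "b2": 2}), ann)
        assert "C" not in fit.estimable_groups
        assert set(fit.group_means) == {"A", "B"}

    def test_paired_blocking_reduces_variance_keeps_difference(self):
        subj = {"a1": "s1", "a2": "s2", "b1": "s1", "b2": "s2"}
        ann_paired = make_annotation({"A": ["a1", "a2"], "B": ["b1", "b2"]},
                                     subject=subj, control="A")
        # subject s2 shifted +1 in both groups; true group difference 1
        y = series({"a1": 2.0, "a2": 3.0, "b1": 1.0, "b2": 2.0})
        paired = fit_group_model(y, ann_paired)
        unpaired = fit_group_model(y, AB)
        diff_paired = paired.group_means["A"] - paired.group_means["B"]
        diff_unpaired = unpaired.group_means["A"] - unpaired.group_means["B"]
        assert diff_paired == pytest.approx(diff_unpaired)
        assert diff_paired == pytest.approx(1.0)
        assert paired.sigma2 < unpaired.sigma2 + 1e-12

    def test_no_observations_rejected(self):
        with pytest.raises(ValueError, match="no observations"):
            fit_group_model(pd.Series(dtype=float), AB)


class TestModeration:
    def _fits(self, sigma2s, df=3):
        fits = []
        for i, s2 in enumerate(sigma2s):
            fits.append(
                type("F", (), {"sigma2": s2, "df_resid": df, "protein_id": str(i)})()
            )
        return fits

    def test_prior_var_is_mean_sigma2(self):
        mod = moderate_variance(self._fits([1.0, 2.0, 3.0]), prior_df=10)
        assert mod.prior_var == pytest.approx(2.0)

    def test_prior_df_zero_reduces_to_raw(self):
        mod = ModerationParams(prior_df=0.0, prior_var=2.0)
        assert mod.shrink(5.0, 3.0) == (5.0, 3.0)

    def test_huge_prior_df_collapses_to_prior_var(self):
        mod = ModerationParams(prior_df=1e9, prior_var=2.0)
        s2, df = mod.shrink(100.0, 3.0)
        assert s2 == pytest.approx(2.0, rel=1e-6)

    def test_prior_df_equal_df_gives_midpoint(self):
        mod = ModerationParams(prior_df=3.0, prior_var=2.0)
        s2, df = mod.shrink(4.0, 3.0)
        assert s2 == pytest.approx(3.0)
        assert df == 6.0

    def test_no_residual_df_anywhere_fatal(self):
        with pytest.raises(ValueError, match="replicates"):
            moderate_variance(self._fits([np.nan, np.nan], df=0))


class TestTestContrast:
    C = ContrastVector("A_vs_B", {"A": 1.0, "B": -1.0})

    def test_difference_of_means(self):
        fit = fit_group_model(series({"a1": 2, "a2": 2, "b1": 1, "b2": 1}), AB)
        res = evaluate_contrast(fit, self.C, ModerationParams(10.0, 0.5))
        assert res.log2fc == pytest.approx(1.0)
        assert res.status == STATUS_MODELLED

    def test_null_contrast_gives_zero(self):
        c = ContrastVector.__new__(ContrastVector)
        object.__setattr__(c, "name", "zero-ish")
        object.__setattr__(c, "coefficients", {"A": 1.0, "B": 0.0})
        fit = fit_group_model(series({"a1": 2, "a2": 2, "b1": 1, "b2": 1}), AB)
        res = evaluate_contrast(fit, ContrastVector("d", {"A": 1.0, "B": -1.0}),
                            ModerationParams(0.0, 1.0))
        # sigma2 = 0 with no prior: fold change reported, no p-value
        assert res.log2fc == pytest.approx(1.0)
        assert res.p is None

    def test_classical_pooled_t_equivalence(self):
        rng = np.random.default_rng(9)
        ann = make_annotation({"A": ["a1", "a2", "a3"], "B": ["b1", "b2", "b3"]},
                              control="A")
        for _ in range(50):
            ya = rng.normal(0, 1, 3)
            yb = rng.normal(0.5, 1, 3)
            y = series(dict(zip(["a1", "a2", "a3", "b1", "b2", "b3"],
                                np.concatenate([ya, yb]))))
            fit = fit_group_model(y, ann)
            res = evaluate_contrast(fit, self.C, ModerationParams(0.0, 1.0))
            t_ref, p_ref = ss.ttest_ind(ya, yb)
            assert res.t == pytest.approx(t_ref, abs=1e-10)
            assert res.p == pytest.approx(p_ref, abs=1e-10)

    def test_unobserved_group_must_be_routed_elsewhere(self):
        ann = make_annotation({"A": ["a1", "a2"], "B": ["b1", "b2"]}, control="A")
        fit = fit_group_model(series({"a1": 2, "a2": 3}), ann)
        with pytest.raises(ValueError, match="handle_missing_groups"):
            evaluate_contrast(fit, self.C, ModerationParams(10.0, 1.0))


class TestMissingGroups:
    C = ContrastVector("A_vs_B", {"A": 1.0, "B": -1.0})

    def _fit_a_only(self):
        ann = make_annotation({"A": ["a1", "a2"], "B": ["b1", "b2"]}, control="A")
        return fit_group_model(series({"a1": 10.0, "a2": 10.0}), ann)

    def test_omit_reports_protein_without_fold_change(self):
        res = handle_missing_groups(self._fit_a_only(), self.C, strategy="omit",
                                    detection_limit=4.0)
        assert res.status == STATUS_NOT_ESTIMABLE
        assert res.log2fc is None and res.p is None
        assert res.protein_id is not None  # row still exists for output tables

    def test_model_imputes_detection_limit(self):
        res = handle_missing_groups(self._fit_a_only(), self.C, strategy="model",
                                    detection_limit=4.0)
        assert res.status == STATUS_IMPUTED
        assert res.log2fc == pytest.approx(10.0 - 4.0)
        assert res.p is None  # imputed fold changes carry no p-value

    def test_both_groups_missing_not_estimable(self):
        ann = make_annotation({"A": ["a1"], "B": ["b1"], "C": ["c1", "c2"]},
                              control="C")
        fit = fit_group_model(series({"c1": 5.0, "c2": 6.0}), ann)
        for strategy in ("model", "omit"):
            res = handle_missing_groups(fit, self.C, strategy=strategy,
                                        detection_limit=1.0)
            assert res.status == STATUS_NOT_ESTIMABLE


class TestAdjustFdr:
    def test_hand_computed_step_up(self):
        out = adjust_fdr([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(out, [0.04, 0.04, 0.04, 0.04])

    def test_all_ones(self):
        assert np.allclose(adjust_fdr([1.0, 1.0, 1.0]), 1.0)

    def test_invariant_under_duplication(self):
        rng = np.random.default_rng(10)
        p = rng.uniform(size=40)
        single = adjust_fdr(p)
        doubled = adjust_fdr(np.concatenate([p, p]))
        assert np.allclose(doubled[:40], single)
        assert np.allclose(doubled[40:], single)

    def test_monotone_and_bounded(self):
        rng = np.random.default_rng(11)
        p = rng.uniform(size=100)
        out = adjust_fdr(p)
        assert (out >= p - 1e-15).all() and (out <= 1.0).all()
        # discoveries keep their order
        assert np.array_equal(np.argsort(p, kind="stable"),
                              np.argsort(out + p * 1e-12, kind="stable"))

    def test_nan_passthrough(self):
        out = adjust_fdr([0.01, np.nan, 0.5])
        assert np.isnan(out[1]) and not np.isnan(out[0])

    def test_out_of_range_fatal(self):
        with pytest.raises(ValueError):
            adjust_fdr([0.5, 1.5])


def _protein_table(wide: pd.DataFrame) -> TidyQuantTable:
    long = wide.reset_index().melt(id_vars="protein_id", var_name="sample_id",
                                   value_name="intensity").dropna()
    return TidyQuantTable(long, ColumnRoles(peptide_id=None, is_log_transformed=True))


class TestRunDea:
    def _random_run(self, seed=0, n_prot=150, missing_protein=False):
        rng = np.random.default_rng(seed)
        samples = ["a1", "a2", "a3", "b1", "b2", "b3"]
        ann = make_annotation({"A": samples[:3], "B": samples[3:]}, control="A")
        wide = pd.DataFrame(
            rng.normal(10, 1, size=(n_prot, 6)),
            index=[f"P{i:03d}" for i in range(n_prot)], columns=samples,
        )
        if missing_protein:
            wide.iloc[0, 3:] = np.nan  # group B fully missing for P000
        wide.index.name = "protein_id"
        from quantdea.annotation import compile_contrasts

        return _protein_table(wide), ann, compile_contrasts(ann)

    def test_every_protein_once_per_contrast(self):
        table, ann, cs = self._random_run(missing_protein=True)
        result = run_dea(table, ann, cs)
        counts = result.stats.groupby("contrast")["protein_id"].nunique()
        assert (counts == 150).all()
        assert len(result.stats) == 150 * len(cs)

    def test_missing_group_protein_flagged_not_dropped(self):
        table, ann, cs = self._random_run(missing_protein=True)
        result = run_dea(table, ann, cs, missing_strategy="omit")
        row = result.stats[result.stats["protein_id"] == "P000"].iloc[0]
        assert row["status"] == STATUS_NOT_ESTIMABLE
        assert np.isnan(row["log2fc"]) and np.isnan(row["p"])
        result2 = run_dea(table, ann, cs, missing_strategy="model")
        row2 = result2.stats[result2.stats["protein_id"] == "P000"].iloc[0]
        assert row2["status"] == STATUS_IMPUTED
        assert not np.isnan(row2["log2fc"]) and np.isnan(row2["p"])

    def test_null_data_type_one_error_near_nominal(self):
        table, ann, cs = self._random_run(seed=1, n_prot=400)
        result = run_dea(table, ann, cs, prior_df=10.0)
        frac = (result.stats["p"] < 0.05).mean()
        # binomial error around 0.05 with n=400
        assert 0.02 <= frac <= 0.09

    def test_protein_subset_leaves_t_statistics_unchanged(self):
        table, ann, cs = self._random_run(seed=2, n_prot=100)
        full = run_dea(table, ann, cs, prior_df=0.0)
        rng = np.random.default_rng(3)
        keep = set(rng.choice(table.proteins, size=50, replace=False))
        sub_table = table.with_data(
            table.data[table.data["protein_id"].isin(keep)].reset_index(drop=True)
        )
        sub = run_dea(sub_table, ann, cs, prior_df=0.0)
        merged = full.stats.merge(sub.stats, on=["protein_id", "contrast"],
                                  suffixes=("_full", "_sub"))
        assert len(merged) == 50
        # t is computed independently per protein: bit-identical on the subset
        assert (merged["t_full"] == merged["t_sub"]).all()

    def test_deterministic_given_inputs(self):
        table, ann, cs = self._random_run(seed=4)
        r1 = run_dea(table, ann, cs)
        r2 = run_dea(table, ann, cs)
        pd.testing.assert_frame_equal(r1.stats, r2.stats)
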