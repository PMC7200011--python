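import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2

from envnet.differentiation import (
    FeatureTable,
    METRIC_COLUMNS,
    apply_scaler,
    assemble_features,
    coverage_ellipse,
    ellipse_overlap,
    fit_scaler,
    pca,
    scalability_report,
    separability,
    specificity_test,
)
from envnet.errors import ParameterError, ValidationError


def make_table(X, y, columns=None, subs=None):
    columns = columns or [f"f{i}" for i in range(X.shape[1])]
    idx = [f"n{i}" for i in range(len(X))]
    return FeatureTable(
        data=pd.DataFrame(X, index=idx, columns=columns),
        class_labels=pd.Series(y, index=idx),
        sub_class_labels=pd.Series(subs if subs is not None else y, index=idx),
    )


class TestAssembleFeatures:
    def test_column_sets(self, small_confounded_set, small_metrics):
        t3 = assemble_features(small_confounded_set, small_metrics,
                               include_environment=False)
        t4 = assemble_features(small_confounded_set, small_metrics,
                               include_environment=True)
        assert t3.columns == list(METRIC_COLUMNS)
        assert t4.columns == list(METRIC_COLUMNS) + ["temperature_variability"]
        assert not t4.data.isna().any().any()

    def test_undefined_metric_networks_excluded(self, small_confounded_set,
                                                small_metrics):
        import copy

        metrics = copy.deepcopy(small_metrics)
        some_id = small_confounded_set.ids[0]
        metrics[some_id].rel_err_l2_er = np.nan
        t = assemble_features(small_confounded_set, metrics, include_environment=True)
        assert some_id not in t.data.index
        assert t.n_excluded >= 1

    def test_missing_environment_is_an_error(self, small_confounded_set,
                                             small_metrics):
        with pytest.raises(ValidationError, match="missing"):
            assemble_features(small_confounded_set, small_metrics,
                              include_environment=True, env_var="no_such_variable")


class TestScaler:
    def test_sample_sd_convention(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0]})
        scaled = apply_scaler(fit_scaler(df), df)
        assert scaled["a"].tolist() == pytest.approx([-1.0, 0.0, 1.0])

    def test_self_transform_is_standardized(self, rng):
        df = pd.DataFrame(rng.normal(5, 3, size=(40, 3)), columns=list("abc"))
        scaled = apply_scaler(fit_scaler(df), df)
        assert scaled.mean().to_numpy() == pytest.approx(np.zeros(3), abs=1e-12)
        assert scaled.std(ddof=1).to_numpy() == pytest.approx(np.ones(3))

    def test_shifted_table_means_shift_by_delta_over_sd(self, rng):
        df = pd.DataFrame(rng.normal(size=(30, 2)), columns=list("ab"))
        sc = fit_scaler(df)
        shifted = apply_scaler(sc, df + 2.0)
        expected = 2.0 / sc.sds
        assert shifted.mean().to_numpy() == pytest.approx(expected, abs=1e-9)

    def test_constant_column_rejected_by_name(self):
        df = pd.DataFrame({"ok": [1.0, 2.0, 3.0], "flat": [1.0, 1.0, 1.0]})
        with pytest.raises(ValidationError, match="flat"):
            fit_scaler(df)

    def test_reference_recorded(self, rng):
        df = pd.DataFrame(rng.normal(size=(10, 2)), columns=list("ab"))
        assert fit_scaler(df, reference="randomized").reference == "randomized"


class TestPCA:
    def test_perfectly_correlated_columns_one_component(self, rng):
        x = rng.normal(size=60)
        df = pd.DataFrame({"a": x, "b": 2 * x})
        scaled = apply_scaler(fit_scaler(df), df)
        emb = pca(scaled, n_components=2)
        assert emb.explained_variance_ratio[0] == pytest.approx(1.0, abs=1e-12)

    def test_full_reconstruction(self, rng):
        df = pd.DataFrame(rng.normal(size=(50, 4)))
        df.columns = [f"c{i}" for i in range(4)]
        scaled = apply_scaler(fit_scaler(df), df)
        emb = pca(scaled, n_components=4)
        recon = emb.scores.to_numpy() @ emb.loadings.to_numpy().T
        centered = scaled.to_numpy() - scaled.to_numpy().mean(axis=0)
        assert recon == pytest.approx(centered, abs=1e-8)

    def test_sign_convention_fixed(self, rng):
        df = pd.DataFrame(rng.normal(size=(50, 3)), columns=list("abc"))
        scaled = apply_scaler(fit_scaler(df), df)
        emb = pca(scaled, n_components=3)
        for k in emb.loadings.columns:
            col = emb.loadings[k]
            assert col.iloc[np.argmax(np.abs(col.to_numpy()))] > 0

    def test_too_many_components_rejected(self, rng):
        df = pd.DataFrame(rng.normal(size=(10, 2)), columns=list("ab"))
        with pytest.raises(ParameterError):
            pca(df, n_components=3)

    def test_pipeline_invariant_to_row_order(self, rng):
        df = pd.DataFrame(rng.normal(size=(40, 3)), columns=list("abc"))
        perm = rng.permutation(40)
        a = pca(apply_scaler(fit_scaler(df), df), 2).scores
        b = pca(apply_scaler(fit_scaler(df.iloc[perm]), df.iloc[perm]), 2).scores
        assert a.loc[b.index].to_numpy() == pytest.approx(b.to_numpy(), abs=1e-9)


class TestCoverageEllipse:
    def test_isotropic_radius_is_chi2_quantile(self, rng):
        X = rng.standard_normal((100_000, 2))
        e = coverage_ellipse(X, level=0.68)
        r = np.sqrt(chi2.ppf(0.68, 2))  # ~1.5096
        assert e.semi_axes == pytest.approx([r, r], rel=0.02)

    def test_coverage_fraction_near_level(self, rng):
        X = rng.standard_normal((100_000, 2))
        e = coverage_ellipse(X, level=0.68)
        assert e.contains(X).mean() == pytest.approx(0.68, abs=0.01)

    def test_axis_scaling_equivariance(self, rng):
        X = rng.standard_normal((5000, 2))
        e1 = coverage_ellipse(X)
        X2 = X * np.array([2.0, 1.0])
        e2 = coverage_ellipse(X2)
        assert max(e2.semi_axes) == pytest.approx(2 * max(e1.semi_axes), rel=0.05)

    def test_degenerate_data_rejected(self):
        X = np.column_stack([np.arange(10.0), np.arange(10.0)])
        with pytest.raises(ValidationError):
            coverage_ellipse(X)

    def test_identical_ellipses_fully_overlap(self, rng):
        X = rng.standard_normal((500, 2))
        e = coverage_ellipse(X)
        assert ellipse_overlap(e, e) == pytest.approx(1.0, abs=1e-6)


class TestSeparability:
    def test_well_separated_clusters_perfect_accuracy(self, rng):
        X = np.vstack([rng.normal(0, 0.3, (40, 3)), rng.normal(5, 0.3, (40, 3))])
        y = ["mutualistic"] * 40 + ["antagonistic"] * 40
        rep = separability(make_table(X, y), seed=0, n_permutations=99)
        assert rep.cv_accuracy == 1.0
        assert rep.p_value <= 0.01
        assert rep.ellipse_overlap == pytest.approx(0.0, abs=1e-6)

    def test_identical_distributions_near_chance(self, rng):
        hits_acc, hits_p = 0, 0
        for seed in range(8):
            X = rng.standard_normal((200, 3))
            y = ["mutualistic"] * 100 + ["antagonistic"] * 100
            rep = separability(make_table(X, y), seed=seed, n_permutations=99)
            hits_acc += abs(rep.cv_accuracy - 0.5) <= 0.10
            hits_p += rep.p_value > 0.05
        assert hits_acc >= 7
        assert hits_p >= 7

    def test_single_class_rejected(self, rng):
        X = rng.standard_normal((20, 3))
        with pytest.raises(ValidationError):
            separability(make_table(X, ["mutualistic"] * 20), seed=0)

    def test_deterministic_under_seed(self, rng):
        X = np.vstack([rng.normal(0, 1, (30, 3)), rng.normal(1, 1, (30, 3))])
        y = ["mutualistic"] * 30 + ["antagonistic"] * 30
        a = separability(make_table(X, y), seed=3, n_permutations=49)
        b = separability(make_table(X, y), seed=3, n_permutations=49)
        assert a.cv_accuracy == b.cv_accuracy and a.p_value == b.p_value


class TestScalability:
    def test_planted_hierarchy_passes(self, rng):
        centers = {
            ("mutualistic", "pollination"): (0.0, 0.0),
            ("mutualistic", "dispersal"): (1.0, 0.0),
            ("antagonistic", "parasitism"): (6.0, 0.0),
            ("antagonistic", "herbivory"): (7.0, 0.0),
        }
        X, y, s = [], [], []
        for (cls, sub), c in centers.items():
            pts = rng.normal(0, 0.4, (30, 3))
            pts[:, 0] += c[0]
            pts[:, 1] += c[1]
            X.append(pts)
            y += [cls] * 30
            s += [sub] * 30
        rep = scalability_report(make_table(np.vstack(X), y, subs=s))
        assert rep.passes
        assert (rep.table["same_class_dist"] < rep.table["other_class_dist"]).all()

    def test_identically_distributed_sub_classes_do_not_pass_systematically(self, rng):
        passes = 0
        for k in range(10):
            X = rng.standard_normal((120, 3))
            y = ["mutualistic"] * 60 + ["antagonistic"] * 60
            s = (["a", "b"] * 30) + (["c", "d"] * 30)
            passes += scalability_report(make_table(X, y, subs=s)).passes
        assert passes <= 5  # ~ chance: each of 4 sub-classes must be closer in-class

    def test_small_sub_classes_excluded_with_warning(self, rng):
        X = rng.standard_normal((43, 3))
        y = ["mutualistic"] * 22 + ["antagonistic"] * 21
        s = ["a"] * 20 + ["tiny"] * 2 + ["c"] * 21
        with pytest.warns(UserWarning, match="tiny"):
            rep = scalability_report(make_table(X, y, subs=s))
        assert "tiny" not in rep.table.index

    def test_single_sub_class_per_class_flagged_degenerate(self, rng):
        X = rng.standard_normal((40, 3))
        y = ["mutualistic"] * 20 + ["antagonistic"] * 20
        s = ["poll"] * 20 + ["para"] * 20
        with pytest.warns(UserWarning, match="degenerate|class-level"):
            rep = scalability_report(make_table(X, y, subs=s))
        assert rep.degenerate


class TestSpecificity:
    def test_randomized_architectures_near_chance(self, small_confounded_set):
        rep = specificity_test(small_confounded_set, R=40, seed=11,
                               n_permutations=99)
        assert rep.scaler_reference == "randomized"
        assert abs(rep.cv_accuracy - 0.5) <= 0.15  # small set: wide tolerance
        assert rep.p_value > 0.01

    def test_empirical_scaling_flagged_as_anti_pattern(self, small_confounded_set):
        with pytest.warns(UserWarning, match="collider"):
            rep = specificity_test(small_confounded_set, R=10, seed=2,
                                   n_permutations=19,
                                   scaling_reference="empirical")
        assert rep.scaler_reference == "empirical"
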