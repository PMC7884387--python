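import numpy as np
import pytest

from paleoattrib import synthetic as syn
from paleoattrib.gmm import (
    BetweenGroupPCA,
    CanonicalVariateAnalysis,
    GeneralizedProcrustesAnalysis,
    allometry_test,
    bgpca,
    classify,
    cv_bgpca,
    cva,
    gpa,
    pca,
    project_unknown,
    resample_curve,
    select_pcs,
)


def random_rigid_motion(rng, reflect=False):
    q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
    if (np.linalg.det(q) < 0) != reflect:
        q[:, 0] = -q[:, 0]
    return q, rng.uniform(-10, 10, 3), rng.uniform(0.5, 2.0)


class TestResampleCurve:
    def test_straight_segment(self):
        out = resample_curve([(0, 0, 0), (1, 0, 0)], 3)
        np.testing.assert_allclose(out[:, 0], [0, 0.5, 1])

    def test_already_equispaced_is_identity(self):
        pts = np.column_stack([np.linspace(0, 2, 7), np.zeros(7), np.linspace(0, 1, 7)])
        np.testing.assert_allclose(resample_curve(pts, 7), pts, atol=1e-12)

    def test_quarter_circle_equal_chords(self):
        theta = np.linspace(0, np.pi / 2, 2000)
        circle = np.column_stack([np.cos(theta), np.sin(theta), np.zeros_like(theta)])
        out = resample_curve(circle, 5)
        chords = np.linalg.norm(np.diff(out, axis=0), axis=1)
        assert np.ptp(chords) < 1e-6
        np.testing.assert_allclose(out[0], circle[0], atol=1e-12)
        np.testing.assert_allclose(out[-1], circle[-1], atol=1e-12)

    def test_zero_length_polyline_rejected(self):
        with pytest.raises(ValueError, match="zero length"):
            resample_curve([(1, 1, 1), (1, 1, 1)], 3)


class TestGPA:
    def test_single_configuration_kept_up_to_rotation(self, rng):
        x = rng.normal(size=(10, 3))
        al = gpa(x[None])
        xc = x - x.mean(0)
        xc /= np.sqrt((xc**2).sum())
        # shape identical: zero Procrustes distance to the centered, scaled input
        u, s, vt = np.linalg.svd(al.procrustes_coords[0].T @ xc)
        assert s.sum() == pytest.approx(1.0, abs=1e-9)

    def test_rotated_scaled_pair_has_zero_procrustes_distance(self, rng):
        x = rng.normal(size=(8, 3))
        q, t, c = random_rigid_motion(rng)
        al = gpa(np.stack([x, c * x @ q.T + t]))
        d = np.linalg.norm(al.procrustes_coords[0] - al.procrustes_coords[1])
        assert d < 1e-9

    def test_output_invariant_under_rigid_motions_and_scalings(self, shape_sample, rng):
        base = GeneralizedProcrustesAnalysis().fit(shape_sample.configs)
        moved = np.empty_like(shape_sample.configs)
        for i, cfg in enumerate(shape_sample.configs):
            q, t, c = random_rigid_motion(rng)
            moved[i] = c * cfg @ q.T + t
        again = GeneralizedProcrustesAnalysis().fit(moved)
        assert np.abs(base.residuals_ - again.residuals_).max() < 1e-8
        np.testing.assert_allclose(base.consensus_, again.consensus_, atol=1e-8)

    def test_alignment_invariants(self, shape_sample):
        al = gpa(shape_sample.configs)
        assert np.linalg.norm(al.consensus.mean(axis=0)) < 1e-9
        sizes = np.sqrt((al.procrustes_coords**2).sum(axis=(1, 2)))
        np.testing.assert_allclose(sizes, 1.0, atol=1e-9)
        assert np.abs(al.residuals.mean(axis=0)).max() < 1e-8

    def test_centroid_sizes_are_prescaling(self, rng):
        x = rng.normal(size=(6, 3))
        al = gpa(np.stack([x, 3.0 * x]))
        assert al.centroid_sizes[1] == pytest.approx(3 * al.centroid_sizes[0])

    def test_degenerate_configuration_rejected(self):
        with pytest.raises(ValueError, match="degenerate|coincide"):
            gpa(np.zeros((2, 5, 3)))

    def test_too_few_landmarks_rejected(self, rng):
        with pytest.raises(ValueError, match="at least 4"):
            gpa(rng.normal(size=(3, 3, 3)))


class TestPCA:
    def test_one_dimensional_residuals_explain_everything(self, rng):
        t = rng.normal(size=20)
        direction = np.array([1.0, 2.0, 0.5, -1.0])
        model = pca(np.outer(t, direction))
        assert model.explained[0] == pytest.approx(1.0)

    def test_explained_fractions_sum_to_one(self, shape_sample):
        model = pca(gpa(shape_sample.configs))
        assert model.explained.sum() == pytest.approx(1.0, abs=1e-9)

    def test_known_two_variable_covariance(self):
        a, b = 1.5, np.sqrt(0.75)
        X = np.array([[a, a], [-a, -a], [b, -b], [-b, b]])  # sample cov [[2,1],[1,2]]
        model = pca(X)
        ev = model.estimator.explained_variance_
        np.testing.assert_allclose(ev, [3.0, 1.0], atol=1e-12)
        np.testing.assert_allclose(np.abs(model.axes[0]), [1, 1] / np.sqrt(2), atol=1e-12)
        np.testing.assert_allclose(np.abs(model.axes[1]), [1, 1] / np.sqrt(2), atol=1e-12)

    def test_reconstruction_from_all_axes(self, shape_sample):
        al = gpa(shape_sample.configs)
        model = pca(al)
        recon = model.scores @ model.axes + model.center
        np.testing.assert_allclose(recon, al.residuals, atol=1e-9)

    def test_single_specimen_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            pca(np.zeros((1, 6)))


class TestSelectPcs:
    @pytest.mark.parametrize(
        "fractions,target,expected",
        [((0.5, 0.3, 0.1, 0.1), 0.9, 3), ((0.5, 0.3, 0.1, 0.1), 1.0, 4), ((1.0,), 0.9, 1)],
    )
    def test_cumulative_selection(self, fractions, target, expected):
        assert select_pcs(fractions, target) == expected

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            select_pcs([])


class TestBetweenGroupPCA:
    def test_two_groups_have_one_informative_axis(self, shape_sample):
        model = bgpca(gpa(shape_sample.configs), shape_sample.labels)
        assert model.axes.shape[0] == 1

    def test_identical_group_means_score_at_origin(self, rng):
        X = rng.normal(size=(12, 6))
        X[6:] = X[:6]  # group B duplicates group A: identical means
        y = np.array(["A"] * 6 + ["B"] * 6)
        est = BetweenGroupPCA().fit(X, y)
        for c in est.classes_:
            np.testing.assert_allclose(est.group_score_means_[c], 0.0, atol=1e-10)

    def test_recovers_injected_offset_direction(self, shape_sample):
        al = gpa(shape_sample.configs)
        model = bgpca(al, shape_sample.labels)
        # true between-group direction = difference of generating directions
        delta = (0.5 * shape_sample.effect_directions["A"]
                 - 0.5 * shape_sample.effect_directions["B"])
        # the injected effects live on the pre-alignment scale; compare angles
        # through the empirical group mean difference instead
        ga = al.residuals[shape_sample.labels == "A"].mean(axis=0)
        gb = al.residuals[shape_sample.labels == "B"].mean(axis=0)
        emp = ga - gb
        cosang = abs(model.axes[0] @ emp) / np.linalg.norm(emp)
        assert np.degrees(np.arccos(min(cosang, 1.0))) < 5.0

    def test_single_group_rejected(self, rng):
        with pytest.raises(ValueError, match="2 groups"):
            BetweenGroupPCA().fit(rng.normal(size=(5, 4)), np.array(["A"] * 5))


class TestClassification:
    def test_specimen_at_group_mean_gets_maximal_posterior(self, shape_sample):
        al = gpa(shape_sample.configs)
        model = bgpca(al, shape_sample.labels)
        ga = al.residuals[shape_sample.labels == "A"].mean(axis=0)
        res = classify(model, ga)
        assert res.table["predicted"].iloc[0] == "A"
        assert res.table["posterior_A"].iloc[0] > res.table["posterior_B"].iloc[0]

    def test_equidistant_specimen_ties_at_half(self):
        X = np.array([[-1, 0.1], [-1, -0.1], [1, 0.1], [1, -0.1]], float)
        y = np.array(["A", "A", "B", "B"])
        est = BetweenGroupPCA().fit(X, y)
        t = est.classify(np.array([[0.0, 0.0]]))
        assert t["posterior_A"].iloc[0] == pytest.approx(0.5)
        assert t["posterior_B"].iloc[0] == pytest.approx(0.5)
        assert bool(t["tie"].iloc[0])
        assert t["predicted"].iloc[0] == "A"  # deterministic name-order tie-break

    def test_well_separated_groups_posterior_above_99(self, shape_sample):
        al = gpa(shape_sample.configs)
        est = BetweenGroupPCA().fit(al.residuals, shape_sample.labels)
        post = est.predict_proba(al.residuals[shape_sample.labels == "A"])
        assert post[:, 0].min() > 0.99


class TestCrossValidatedBgPCA:
    def test_far_groups_classify_above_95_percent(self, shape_sample):
        res = cv_bgpca(gpa(shape_sample.configs), shape_sample.labels)
        assert min(res.summary.values()) >= 95.0

    def test_duplicate_specimens_classify_perfectly(self, rng):
        a = rng.normal(size=6)
        b = rng.normal(size=6)
        X = np.stack([a, a, b, b])
        res = cv_bgpca(X, np.array(["A", "A", "B", "B"]))
        assert res.accuracy == 100.0

    def test_singleton_group_error_names_group(self, rng):
        X = rng.normal(size=(5, 4))
        with pytest.raises(ValueError, match="'B'"):
            cv_bgpca(X, np.array(["A", "A", "A", "A", "B"]))


class TestCVA:
    def test_two_gaussians_on_one_variable(self, rng):
        n = 50
        X = np.concatenate([rng.normal(-5, 1, n), rng.normal(5, 1, n)])[:, None]
        y = np.array(["lo"] * n + ["hi"] * n)
        model, res = cva(X, y)
        assert model.axes.shape == (1, 1)
        assert res.accuracy >= 99.0  # two-Gaussian Bayes error ~ Phi(-5)

    def test_axis_count_is_min_groups_minus_one_and_m(self, rng):
        X = rng.normal(size=(30, 4))
        y = np.repeat(["A", "B", "C"], 10)
        model, _ = cva(X, y)
        assert model.axes.shape[0] == 2

    def test_spherical_within_covariance_matches_bgpca_axes(self, rng):
        # whiten within-group scatter exactly so pooled W = I
        p, npg = 5, 10
        means = {"A": np.zeros(p), "B": np.r_[4.0, np.zeros(p - 1)],
                 "C": np.r_[0.0, 2.5, np.zeros(p - 2)]}
        y = np.repeat(list(means), npg)
        D = rng.normal(size=(3 * npg, p))
        for c in means:
            D[y == c] -= D[y == c].mean(axis=0)
        pooled = D.T @ D / (len(y) - 3)
        D = D @ np.linalg.inv(np.linalg.cholesky(pooled)).T
        X = D + np.stack([means[c] for c in y])
        cv_model, _ = cva(X, y)
        bg_model = bgpca(X, y)
        for k in range(2):
            a = cv_model.axes[k] / np.linalg.norm(cv_model.axes[k])
            b = bg_model.axes[k]
            assert abs(abs(a @ b) - 1.0) < 1e-6

    def test_too_many_variables_reports_feasible_maximum(self, rng):
        X = rng.normal(size=(10, 9))
        y = np.repeat(["A", "B"], 5)
        with pytest.raises(ValueError, match="at most 8"):
            CanonicalVariateAnalysis().fit(X, y)


class TestProjectUnknown:
    def test_training_specimen_reproduces_training_scores(self, shape_sample):
        align = GeneralizedProcrustesAnalysis().fit(shape_sample.configs)
        model = bgpca(align.aligned_(), shape_sample.labels)
        r = align.transform(shape_sample.configs[:5])
        np.testing.assert_allclose(
            project_unknown(model, r), model.scores[:5], atol=1e-9
        )

    def test_consensus_projects_to_origin(self, shape_sample):
        al = gpa(shape_sample.configs)
        model = pca(al)
        scores = project_unknown(model, np.zeros(al.residuals.shape[1]))
        assert np.abs(scores).max() < 1e-6

    def test_unknown_from_group_classified_with_high_posterior(self):
        train = syn.simulate_shape_groups(
            syn.ShapeSimSpec(n_per_group=20, seed=11, noise_sd=0.05)
        )
        extra = syn.simulate_shape_groups(
            syn.ShapeSimSpec(
                n_per_group=1, seed=99, noise_sd=0.05,
                group_effects={g: (d, 0.5) for g, d in train.effect_directions.items()},
            )
        )
        align = GeneralizedProcrustesAnalysis().fit(train.configs)
        est = BetweenGroupPCA().fit(align.aligned_().residuals, train.labels)
        unk = extra.configs[extra.labels == "A"]
        table = est.classify(align.transform(unk))
        assert table["predicted"].iloc[0] == "A"
        assert table["posterior_A"].iloc[0] > 0.9

    def test_landmark_count_mismatch_rejected(self, shape_sample):
        model = pca(gpa(shape_sample.configs))
        with pytest.raises(ValueError, match="does not match"):
            project_unknown(model, np.zeros(12))


class TestAllometry:
    def test_exact_linear_dependence(self, rng):
        cs = rng.uniform(10, 20, 30)
        res = allometry_test(2.0 * cs, cs)
        assert res["r_squared"].iloc[0] == pytest.approx(1.0)
        assert res["p_value"].iloc[0] < 1e-20
        assert res["slope"].iloc[0] == pytest.approx(2.0)

    def test_independent_scores_show_no_allometry(self):
        rng = np.random.default_rng(42)
        r2s, ps = [], []
        for _ in range(20):
            cs = rng.uniform(10, 20, 100)
            res = allometry_test(rng.normal(size=100), cs)
            r2s.append(res["r_squared"].iloc[0])
            ps.append(res["p_value"].iloc[0])
        assert np.median(r2s) < 0.1
        assert np.mean(np.asarray(ps) < 0.05) <= 0.25  # around the nominal 5%

    def test_constant_centroid_size_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            allometry_test(np.arange(5.0), np.full(5, 3.0))
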