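import shutil
import subprocess

import numpy as np
import pytest
from scipy.stats import norm

from emtscape.subpopulations import (
    DEFAULT_STRUCTURES,
    STRUCTURES,
    MixtureModel,
    assign_clusters,
    compare_structures,
    fit_gmm,
    label_semantic,
    select_model,
)

FIG_GEOMETRY = {
    "E": (0.45, -0.35),
    "I0": (-0.15, -0.30),
    "I1": (0.30, 0.25),
    "I2": (-0.05, 0.35),
    "M": (-0.50, 0.55),
}


def make_model(means, variances=None, weights=None):
    means = np.asarray(means, float)
    K = means.shape[0]
    return MixtureModel(
        K=K,
        structure="EII",
        weights=np.full(K, 1.0 / K) if weights is None else np.asarray(weights),
        means=means,
        variances=np.full((K, 2), 0.01) if variances is None else np.asarray(variances),
        loglik=0.0,
        n_obs=100,
    )


class TestFitGmm:
    def test_single_component_is_closed_form_gaussian(self):
        rng = np.random.default_rng(0)
        pts = rng.normal([1.0, 2.0], [0.5, 0.8], size=(200, 2))
        m = fit_gmm(pts, 1, "VVI")
        assert np.allclose(m.means[0], pts.mean(axis=0), atol=1e-10)
        ref = sum(
            norm.logpdf(pts[:, j], pts[:, j].mean(), pts[:, j].std()).sum()
            for j in range(2)
        )
        assert m.loglik == pytest.approx(ref, abs=1e-8)
        # BIC by hand: K=1 VVI has 2 means + 2 variances, no free weight
        assert m.bic == pytest.approx(-2 * ref + 4 * np.log(200), abs=1e-6)

    def test_separated_blobs_recovered(self):
        rng = np.random.default_rng(1)
        pts = np.vstack(
            [rng.normal([0, 0], 0.1, (250, 2)), rng.normal([1, 1], 0.1, (250, 2))]
        )
        m = fit_gmm(pts, 2, "EII", seed=1)
        got = m.means[np.argsort(m.means[:, 0])]
        assert np.abs(got - [[0, 0], [1, 1]]).max() < 0.05

    def test_loglik_not_degraded_by_more_iterations(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(300, 2))
        short = fit_gmm(pts, 3, "VVI", seed=2, max_iter=5)
        long = fit_gmm(pts, 3, "VVI", seed=2, max_iter=400)
        assert long.loglik >= short.loglik - 1e-9

    @pytest.mark.parametrize("structure", STRUCTURES)
    def test_structure_constraints_hold_exactly(self, structure):
        rng = np.random.default_rng(3)
        pts = np.vstack(
            [rng.normal([0, 0], [0.2, 0.5], (200, 2)), rng.normal([2, 1], 0.3, (200, 2))]
        )
        m = fit_gmm(pts, 2, structure, seed=3)
        v = m.variances
        if structure == "EII":
            assert np.allclose(v, v[0, 0])
        elif structure == "VII":
            assert np.allclose(v[:, 0], v[:, 1])
        elif structure == "EEI":
            assert np.allclose(v[0], v[1])
        elif structure == "VEI":
            # shared shape: rows proportional
            assert np.allclose(v[0] / v[0].prod() ** 0.5, v[1] / v[1].prod() ** 0.5)
        elif structure == "EVI":
            # shared volume: equal row geometric means
            assert np.allclose(v[0].prod(), v[1].prod())

    def test_determinism_under_fixed_seed(self):
        rng = np.random.default_rng(4)
        pts = rng.normal(size=(200, 2))
        a = fit_gmm(pts, 3, "EII", init="kmeans", seed=7)
        b = fit_gmm(pts, 3, "EII", init="kmeans", seed=7)
        assert np.array_equal(a.means, b.means)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="5K"):
            fit_gmm(np.zeros((9, 2)), 2, "EII")


class TestSelectModel:
    def test_bic_is_lower_is_better_and_matches_hand_formula(self):
        rng = np.random.default_rng(5)
        pts = rng.normal(size=(300, 2))
        model, table = select_model(pts, K_range=[1, 2], structures=["EII"])
        m1 = fit_gmm(pts, 1, "EII")
        # K=1 EII: 2 means + 1 variance
        assert table.loc[1, "EII"] == pytest.approx(
            -2 * m1.loglik + 3 * np.log(300), abs=1e-6
        )
        assert model.bic == table.min().min()

    def test_failed_candidates_recorded_not_fatal(self):
        rng = np.random.default_rng(6)
        pts = rng.normal(size=(30, 2))
        # K=9 violates n >= 5K and must show up as NaN, not raise
        model, table = select_model(pts, K_range=[1, 9], structures=["EII"])
        assert np.isnan(table.loc[9, "EII"])
        assert model.K == 1


class TestAssignClusters:
    def test_point_at_dominant_mean_is_certain(self):
        m = make_model([[0.0, 0.0], [5.0, 5.0]])
        a = assign_clusters(m, np.array([[0.0, 0.0]]))
        assert a.uncertainty[0] < 0.01
        assert a.labels[0] == 0

    def test_single_component_has_zero_uncertainty(self):
        m = make_model([[0.0, 0.0]])
        a = assign_clusters(m, np.random.default_rng(0).normal(size=(20, 2)))
        assert np.allclose(a.posteriors, 1.0)
        assert np.allclose(a.uncertainty, 0.0)

    def test_posterior_rows_normalized(self):
        m = make_model([[0, 0], [1, 0], [0, 1]])
        pts = np.random.default_rng(1).normal(0.3, 0.5, size=(50, 2))
        a = assign_clusters(m, pts)
        assert np.allclose(a.posteriors.sum(axis=1), 1.0, atol=1e-10)


class TestSemanticLabels:
    def test_five_state_geometry_labelled_correctly(self):
        m = make_model(list(FIG_GEOMETRY.values()))
        assert label_semantic(m) == {0: "E", 1: "I0", 2: "I1", 3: "I2", 4: "M"}

    def test_component_storage_order_irrelevant(self):
        names = list(FIG_GEOMETRY)
        perm = [3, 0, 4, 2, 1]
        m = make_model([FIG_GEOMETRY[names[i]] for i in perm])
        mapping = label_semantic(m)
        assert [mapping[k] for k in range(5)] == [names[i] for i in perm]

    def test_four_state_model_has_no_i2(self):
        m = make_model([FIG_GEOMETRY[n] for n in ("E", "I0", "I1", "M")])
        assert set(label_semantic(m).values()) == {"E", "I0", "I1", "M"}

    def test_other_k_directed_to_integer_labels(self):
        m = make_model([[0, 0], [1, 1], [2, 2]])
        with pytest.raises(ValueError, match="integer labels"):
            label_semantic(m)


class TestCompareStructures:
    def test_identical_and_relabelled_partitions_agree_fully(self):
        labels = np.array([0, 0, 1, 1, 2, 2] * 10)
        relabel = (labels + 1) % 3
        out = compare_structures({"a": labels, "b": labels.copy(), "c": relabel})
        assert np.allclose(out.to_numpy(), 1.0)

    def test_independent_labelings_score_near_zero(self):
        rng = np.random.default_rng(8)
        a = rng.integers(0, 5, 1000)
        b = rng.integers(0, 5, 1000)
        ari = compare_structures({"a": a, "b": b}).loc["a", "b"]
        assert -0.05 < ari < 0.05

    def test_mismatched_samples_rejected(self):
        with pytest.raises(ValueError, match="different sample"):
            compare_structures({"a": np.zeros(10), "b": np.zeros(12)})


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="R not available")
def test_eii_fit_matches_mclust_oracle(tmp_path):
    """Independent oracle: R's model-based clustering on the same points."""
    rng = np.random.default_rng(5)
    pts = np.vstack(
        [rng.normal([0, 0], 0.1, (150, 2)), rng.normal([1, 1], 0.1, (150, 2))]
    )
    csv = tmp_path / "pts.csv"
    np.savetxt(csv, pts, delimiter=",")
    script = (
        'suppressMessages(library(mclust));'
        f'x <- as.matrix(read.csv("{csv}", header=FALSE));'
        'fit <- Mclust(x, G=2, modelNames="EII", verbose=FALSE);'
        'cat(fit$loglik, fit$parameters$mean, fit$parameters$variance$sigmasq, "\\n")'
    )
    out = subprocess.run(
        ["Rscript", "-e", script], capture_output=True, text=True, timeout=300
    )
    assert out.returncode == 0, out.stderr
    vals = np.array([float(v) for v in out.stdout.split()])
    m = fit_gmm(pts, 2, "EII")
    ours_means = m.means[np.argsort(m.means[:, 0])].T.ravel(order="F")
    ref_means = vals[1:5].reshape(2, 2, order="F")
    ref_means = ref_means[:, np.argsort(ref_means[0])].ravel(order="F")
    assert m.loglik == pytest.approx(vals[0], abs=1e-4)
    assert np.allclose(ours_means, ref_means, atol=1e-4)
    assert m.variances[0, 0] == pytest.approx(vals[5], abs=1e-6)
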