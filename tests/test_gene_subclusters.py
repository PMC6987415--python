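import warnings

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from emtscape import synthetic_data as sd
from emtscape.genesets import GeneSet
from emtscape.gene_subclusters import (
    SOMGrid,
    classify_nodes,
    condition_profiles,
    score_subclusters,
    subcluster_nodes,
    train_som,
)
from emtscape.scoring import score_matrix


def run_subcluster_pipeline(seed):
    """Panel -> SOM -> node labels -> subclusters, with truth attached."""
    matrix, truth = sd.generate_perturbation_panel(seed=seed)
    profiles = condition_profiles(matrix)
    grid = train_som(profiles, seed=seed)
    e = GeneSet("E", frozenset(truth.gene_class.index[truth.gene_class == "E"]))
    m = GeneSet("M", frozenset(truth.gene_class.index[truth.gene_class == "M"]))
    labels = classify_nodes(grid, e, m)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        subs = subcluster_nodes(grid, labels, "E") + subcluster_nodes(grid, labels, "M")
    return grid, labels, subs, truth


class TestTrainSom:
    def test_two_archetypes_occupy_disjoint_regions(self):
        rng = np.random.default_rng(0)
        a = np.tile([1.0, -1.0, 1.0, -1.0], (100, 1))
        b = np.tile([-1.0, 1.0, -1.0, 1.0], (100, 1))
        X = np.vstack([a, b]) + rng.normal(0, 0.2, (200, 4))
        grid = train_som(X, shape=(6, 6), epochs=40, seed=0)
        assert set(grid.bmu[:100]).isdisjoint(set(grid.bmu[100:]))

    def test_retraining_is_deterministic(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(80, 5))
        g1 = train_som(X, shape=(5, 5), epochs=30, seed=3)
        g2 = train_som(X, shape=(5, 5), epochs=30, seed=3)
        assert np.array_equal(g1.bmu, g2.bmu)
        assert np.allclose(g1.codebooks, g2.codebooks)

    def test_quantization_error_decreases_on_structured_data(self):
        rng = np.random.default_rng(2)
        arch = np.array([[1.5, -1.5, 0, 0], [0, 0, 1.5, -1.5], [-1.5, 0, 0, 1.5]])
        X = np.repeat(arch, 50, axis=0) + rng.normal(0, 0.3, (150, 4))
        grid = train_som(X, shape=(6, 6), epochs=50, seed=2)
        # epoch 0 reflects the data-sampled init before neighbourhood
        # smoothing; from epoch 1 on the error shrinks (batch-update slack)
        q = np.asarray(grid.quantization_errors[1:])
        assert q[-1] < q[0]
        assert (np.diff(q) <= 0.02).all()

    def test_constant_profile_gene_rejected_by_name(self):
        X = pd.DataFrame(
            [[1.0, 2.0, 3.0], [5.0, 5.0, 5.0]], index=["ok", "FLATGENE"]
        )
        with pytest.raises(ValueError, match="FLATGENE"):
            train_som(X)


class TestClassifyNodes:
    def _tiny_grid(self, bmu, gene_ids, shape=(2, 2)):
        return SOMGrid(
            shape=shape,
            codebooks=np.zeros((shape[0] * shape[1], 3)),
            bmu=np.asarray(bmu),
            gene_ids=gene_ids,
            quantization_errors=[0.0],
            seed=0,
            epochs=0,
        )

    def test_majority_count_and_ratio(self):
        genes = [f"e{i}" for i in range(5)] + ["m0"]
        grid = self._tiny_grid([0] * 6, genes)
        labels = classify_nodes(
            grid,
            GeneSet("E", frozenset(g for g in genes if g.startswith("e"))),
            GeneSet("M", frozenset({"m0"})),
        )
        assert labels.loc[0, "label"] == "E"
        assert labels.loc[0, "majority_ratio"] == pytest.approx(5 / 6)

    def test_annotation_free_node_inherits_nearest_label(self):
        genes = ["e0", "e1", "x0"]
        # node 0 holds E genes; node 3 holds an unannotated gene
        grid = self._tiny_grid([0, 0, 3], genes)
        labels = classify_nodes(
            grid, GeneSet("E", frozenset({"e0", "e1"})), GeneSet("M", frozenset({"zz"}))
        )
        assert labels.loc[3, "label"] == "E"
        assert labels.loc[3, "imputed"]

    def test_tied_node_resolved_by_neighbours(self):
        genes = ["e0", "e1", "e2", "m0", "tie_e", "tie_m"]
        # node 0: pure E majority neighbourhood; node 1: 1 E + 1 M tie
        grid = self._tiny_grid([0, 0, 0, 0, 1, 1], genes)
        labels = classify_nodes(
            grid,
            GeneSet("E", frozenset({"e0", "e1", "e2", "tie_e"})),
            GeneSet("M", frozenset({"m0", "tie_m"})),
        )
        assert labels.loc[1, "label"] == "E"

    def test_no_annotations_at_all_rejected(self):
        grid = self._tiny_grid([0, 1], ["x", "y"])
        with pytest.raises(ValueError, match="annotated"):
            classify_nodes(
                grid, GeneSet("E", frozenset({"a"})), GeneSet("M", frozenset({"b"}))
            )


class TestSubclusterNodes:
    def test_three_archetypes_recovered(self):
        rng = np.random.default_rng(4)
        arch = np.array([[2, 0, 0, 0], [0, 2, 0, 0], [0, 0, 2, 0]], float)
        X = np.repeat(arch, 60, axis=0) + rng.normal(0, 0.25, (180, 4))
        grid = train_som(X, shape=(8, 8), epochs=50, seed=4)
        labels = pd.DataFrame(
            {"label": ["E"] * grid.n_nodes}, index=pd.RangeIndex(grid.n_nodes)
        )
        subs = subcluster_nodes(grid, labels, "E")
        assert len(subs) == 3
        truth = np.repeat([0, 1, 2], 60)
        pred_map = {g: s.name for s in subs for g in s.member_genes}
        pred = [pred_map[f"g{i}"] for i in range(180)]
        assert adjusted_rand_score(truth, pred) > 0.9

    def test_identical_codebooks_collapse_to_one(self):
        grid = SOMGrid(
            shape=(2, 3),
            codebooks=np.ones((6, 4)),
            bmu=np.arange(6),
            gene_ids=[f"g{i}" for i in range(6)],
            quantization_errors=[0.0],
            seed=0,
            epochs=0,
        )
        labels = pd.DataFrame({"label": ["M"] * 6}, index=pd.RangeIndex(6))
        subs = subcluster_nodes(grid, labels, "M")
        assert len(subs) == 1

    def test_subclusters_partition_class_genes(self):
        _, labels, subs, truth = run_subcluster_pipeline(seed=0)
        e_subs = [s for s in subs if s.class_label == "E"]
        covered = [g for s in e_subs for g in s.member_genes]
        assert len(covered) == len(set(covered))
        assert set(covered) == set(truth.gene_class.index[truth.gene_class == "E"])


class TestScoreSubclusters:
    def test_whole_class_subcluster_equals_class_score(self):
        matrix, truth = sd.generate_timecourse(
            n_e_genes=40, n_m_genes=30, n_background=60, seed=6
        )
        from emtscape.gene_subclusters import GeneSubcluster

        e_genes = sorted(truth.gene_class.index[truth.gene_class == "E"])
        sub = GeneSubcluster("E1", "E", [], e_genes)
        sub_scores = score_subclusters(matrix, [sub]).scores
        ref = score_matrix(matrix, sd.signature_sets(40, 30)).scores
        assert np.allclose(sub_scores["E1"].to_numpy(), ref["E"].to_numpy())
        assert (sub_scores.abs() <= 1).all().all()


def test_end_to_end_subcluster_recovery():
    """The six gate-model subclusters are recovered almost exactly."""
    _, _, subs, truth = run_subcluster_pipeline(seed=1)
    pred = {g: s.name for s in subs for g in s.member_genes}
    genes = list(truth.subcluster.index)
    ari = adjusted_rand_score(
        [truth.subcluster[g] for g in genes], [pred.get(g, "?") for g in genes]
    )
    assert ari > 0.8
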