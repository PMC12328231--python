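"""Stage tensors, temporal-class rules, trajectory clustering, proportions."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from nichemapper.temporal import (
    StageTensor,
    classify_trajectory,
    cluster_trajectories,
    population_proportions,
    stage_tensor,
)

STAGES = ("naive", "initiation", "expansion", "end")


def make_tensor(det, mean=None, populations=("A", "B")):
    """Tensor from detection (and optional mean) arrays, pop x stage per gene."""
    det = np.asarray(det, float)[None, :, :]
    mean = det.copy() if mean is None else np.asarray(mean, float)[None, :, :]
    return StageTensor(
        genes=["g"], populations=list(populations), stages=STAGES,
        mean=mean, detection=det,
    )


class TestStageTensor:
    @staticmethod
    def toy():
        # 12 cells: 2 populations x 4 stages, uneven cell counts
        rows, meta = [], []
        plan = [
            ("A", "naive", [1, 3]), ("A", "initiation", [2]),
            ("A", "expansion", [4]), ("A", "end", [0]),
            ("B", "naive", [5]), ("B", "initiation", [1, 1]),
            ("B", "expansion", [2]), ("B", "end", [6, 2, 1]),
        ]
        i = 0
        for pop, stage, vals in plan:
            for v in vals:
                rows.append([v, 10 - v])
                meta.append({"cell_id": f"c{i}", "population": pop, "stage": stage})
                i += 1
        counts = pd.DataFrame(rows, columns=["g1", "g2"],
                              index=[m["cell_id"] for m in meta])
        return counts, pd.DataFrame(meta).set_index("cell_id", drop=False)

    def test_hand_computed_means(self):
        counts, meta = self.toy()
        t = stage_tensor(counts, meta, normalize=False)
        gi, ai = t.genes.index("g1"), t.populations.index("A")
        assert t.mean[gi, ai, 0] == pytest.approx(2.0)  # (1+3)/2
        bi = t.populations.index("B")
        assert t.mean[gi, bi, 3] == pytest.approx(3.0)  # (6+2+1)/3
        assert t.detection[gi, ai, 3] == 0.0  # the single end-stage A cell is 0

    def test_constant_gene_constant_slice(self):
        counts, meta = self.toy()
        counts["flat"] = 1
        t = stage_tensor(counts, meta, normalize=False)
        fi = t.genes.index("flat")
        assert np.allclose(t.mean[fi], 1.0)
        assert np.allclose(t.detection[fi], 1.0)

    def test_absent_gene_all_zero(self):
        counts, meta = self.toy()
        counts["ghost"] = 0
        t = stage_tensor(counts, meta, normalize=False)
        gi = t.genes.index("ghost")
        assert np.all(t.mean[gi] == 0) and np.all(t.detection[gi] == 0)

    def test_missing_stage_listed(self):
        counts, meta = self.toy()
        keep = meta["stage"] != "expansion"
        with pytest.raises(ValueError, match="expansion"):
            stage_tensor(counts.loc[keep.to_numpy()], meta.loc[keep.to_numpy()])


class TestClassifyTrajectory:
    def test_lost_template(self):
        t = make_tensor([[0.9, 0.9, 0.9, 0.0], [0.0, 0.0, 0.0, 0.0]])
        assert classify_trajectory(t, "g") == "lost"

    def test_transient_template(self):
        t = make_tensor([[0.0, 0.9, 0.9, 0.0], [0.0, 0.0, 0.0, 0.0]])
        assert classify_trajectory(t, "g") == "transient"

    def test_population_shift_template(self):
        det = [[0.9, 0.9, 0.0, 0.0], [0.0, 0.0, 0.9, 0.9]]
        mean = [[3.0, 3.0, 0.0, 0.0], [0.0, 0.0, 3.0, 3.0]]
        t = make_tensor(det, mean)
        assert classify_trajectory(t, "g") == "population_shift"

    def test_steady_template(self):
        det = [[0.9, 0.9, 0.9, 0.9], [0.0, 0.0, 0.0, 0.0]]
        mean = [[3.0, 3.1, 2.9, 3.0], [0.1, 0.1, 0.1, 0.1]]
        assert classify_trajectory(make_tensor(det, mean), "g") == "steady"

    def test_high_cv_not_steady(self):
        det = [[0.9, 0.9, 0.9, 0.9], [0.0, 0.0, 0.0, 0.0]]
        mean = [[0.5, 6.0, 0.5, 6.0], [0.1, 0.1, 0.1, 0.1]]
        assert classify_trajectory(make_tensor(det, mean), "g") == "unclassified"

    def test_absent_gene_unclassified(self):
        t = make_tensor([[0.0] * 4, [0.0] * 4])
        assert classify_trajectory(t, "g") == "unclassified"

    def test_population_order_invariance(self):
        det = np.array([[0.9, 0.9, 0.0, 0.0], [0.0, 0.0, 0.9, 0.9]])
        mean = np.array([[3.0, 3.0, 0.1, 0.1], [0.1, 0.1, 3.0, 3.0]])
        a = make_tensor(det, mean, populations=("A", "B"))
        # swap population rows and labels together: label must not change
        b = make_tensor(det[::-1], mean[::-1], populations=("B", "A"))
        # tensors store populations as given; reorder b into sorted order
        order = np.argsort(b.populations)
        b = StageTensor(
            genes=b.genes,
            populations=[b.populations[i] for i in order],
            stages=b.stages,
            mean=b.mean[:, order, :],
            detection=b.detection[:, order, :],
        )
        assert classify_trajectory(a, "g") == classify_trajectory(b, "g")


class TestClusterTrajectories:
    @staticmethod
    def tensor_from(trajs, populations=("P",)):
        arr = np.asarray(trajs, float)[:, None, :]
        det = np.full_like(arr, 0.9)
        return StageTensor(
            genes=[f"g{i}" for i in range(len(trajs))],
            populations=list(populations),
            stages=STAGES,
            mean=arr,
            detection=det,
        )

    def test_identical_trajectories_cluster_together(self):
        t = self.tensor_from([[1, 2, 3, 4], [1, 2, 3, 4], [4, 3, 2, 1]])
        res = cluster_trajectories(t, "P", k=2)
        assert res.labels["g0"] == res.labels["g1"] != res.labels["g2"]

    def test_antipodal_trajectories_split(self):
        t = self.tensor_from([[1, 2, 3, 4], [4, 3, 2, 1]])
        res = cluster_trajectories(t, "P", height=1.9)
        assert res.labels["g0"] != res.labels["g1"]

    def test_flat_gene_sent_to_flat_cluster(self):
        t = self.tensor_from([[1, 2, 3, 4], [2, 1, 4, 3], [5, 5, 5, 5]])
        res = cluster_trajectories(t, "P", k=2)
        assert res.labels["g2"] == "flat"

    def test_affine_rescaling_invariance(self):
        base = [[1, 2, 3, 4], [1, 3, 2, 4], [4, 2, 3, 1], [2, 4, 1, 3]]
        t1 = self.tensor_from(base)
        t2 = self.tensor_from([[5 * v + 7 for v in row] for row in base])
        r1 = cluster_trajectories(t1, "P", k=2)
        r2 = cluster_trajectories(t2, "P", k=2)
        genes = [f"g{i}" for i in range(4)]
        l1 = [r1.labels[g] for g in genes]
        l2 = [r2.labels[g] for g in genes]
        assert adjusted_rand_score(l1, l2) == 1.0

    def test_monotone_trend_tags(self):
        t = self.tensor_from([[1, 2, 3, 4], [1.1, 2, 3.2, 4], [9, 5, 3, 1], [8, 6, 2, 1]])
        res = cluster_trajectories(t, "P", k=2)
        tags = set(res.trend.values())
        assert tags == {"increasing", "decreasing"}

    def test_planted_template_recovery(self, rng):
        """40 genes from 3 trajectory templates + noise recovered at k=3."""
        templates = {
            0: np.array([0.0, 1.0, 2.0, 3.0]),
            1: np.array([3.0, 2.0, 1.0, 0.0]),
            2: np.array([0.0, 3.0, 3.0, 0.0]),
        }
        scores = []
        for _ in range(10):
            truth, trajs = [], []
            for i in range(40):
                c = i % 3
                truth.append(c)
                trajs.append(templates[c] + rng.normal(0, 0.25, 4))
            t = self.tensor_from(trajs)
            res = cluster_trajectories(t, "P", k=3)
            labels = [res.labels[f"g{i}"] for i in range(40)]
            scores.append(adjusted_rand_score(truth, labels))
        assert np.mean(scores) >= 0.9

    def test_too_few_variable_genes_rejected(self):
        t = self.tensor_from([[1, 1, 1, 1], [2, 2, 2, 2], [1, 2, 3, 4]])
        with pytest.raises(ValueError, match="nonzero variance"):
            cluster_trajectories(t, "P", k=2)


class TestPopulationProportions:
    @staticmethod
    def meta_from(fracs):
        """fracs: {population: per-stage cell counts}"""
        rows = []
        for pop, counts in fracs.items():
            for stage, n in zip(STAGES, counts):
                rows += [{"population": pop, "stage": stage}] * n
        return pd.DataFrame(rows)

    def test_perfect_monotone_tagged_increasing(self):
        meta = self.meta_from({"up": [10, 20, 30, 40], "down": [90, 80, 70, 60]})
        props, tags = population_proportions(meta)
        assert tags["up"] == "increasing" and tags["down"] == "decreasing"
        assert np.allclose(props.loc["up"], [0.1, 0.2, 0.3, 0.4])

    def test_constant_untagged(self):
        meta = self.meta_from({"a": [10, 10, 10, 10], "b": [10, 10, 10, 10]})
        _, tags = population_proportions(meta)
        assert tags == {"a": "untagged", "b": "untagged"}

    def test_synthetic_drift_recovered(self, default_run, default_cfg):
        tags = default_run.proportion_trends
        assert tags["MSC"] == "increasing"
        assert tags["sinusoidal"] == "decreasing"
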