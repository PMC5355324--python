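"""ROC/AUC correctness, LOOCV, and the robustness ablation protocols."""

import numpy as np
import pandas as pd
import pytest

from conftest import dense_rwr_solve
from lncprior.evaluate import EvaluationConfig, Evaluator, roc_auc
from lncprior.network import PanCancerNetwork
from lncprior.pipeline import PrioritizationPipeline
from lncprior.prioritize import PhenotypeSimilarityMatrix, SeedSet


def pair_counting_auc(scores, positives, negatives):
    """Exhaustive positive-over-negative pair enumeration (ties = 1/2)."""
    wins = 0.0
    for p in positives:
        for n in negatives:
            if scores[p] > scores[n]:
                wins += 1.0
            elif scores[p] == scores[n]:
                wins += 0.5
    return wins / (len(positives) * len(negatives))


class TestRocAuc:
    def test_perfect_separation(self):
        scores = {"p1": 0.9, "p2": 0.8, "n1": 0.2, "n2": 0.1}
        assert roc_auc(scores, {"p1", "p2"}, {"n1", "n2"}).auc == 1.0

    def test_derived_three_quarters(self):
        scores = {"p1": 0.9, "n1": 0.8, "p2": 0.7, "n2": 0.1}
        assert roc_auc(scores, {"p1", "p2"}, {"n1", "n2"}).auc == pytest.approx(0.75)

    def test_all_ties_is_half(self):
        scores = {k: 1.0 for k in "abcd"}
        assert roc_auc(scores, {"a", "b"}, {"c", "d"}).auc == pytest.approx(0.5)

    def test_matches_pair_counting_on_random_instances(self):
        rng = np.random.default_rng(13)
        for _ in range(30):
            n = int(rng.integers(4, 40))
            ids = [f"x{i}" for i in range(n)]
            # coarse grid to force ties
            scores = {i: float(rng.integers(0, 6)) for i in ids}
            k = int(rng.integers(1, n))
            pos, neg = set(ids[:k]), set(ids[k:])
            assert roc_auc(scores, pos, neg).auc == pytest.approx(
                pair_counting_auc(scores, pos, neg)
            )

    def test_complement_property_for_tie_free_scores(self):
        rng = np.random.default_rng(14)
        ids = [f"x{i}" for i in range(20)]
        scores = dict(zip(ids, rng.permutation(20).astype(float)))
        pos, neg = set(ids[:8]), set(ids[8:])
        a = roc_auc(scores, pos, neg).auc
        b = roc_auc({k: -v for k, v in scores.items()}, pos, neg).auc
        assert a + b == pytest.approx(1.0)

    def test_curve_endpoints_and_trapezoid_area(self):
        rng = np.random.default_rng(15)
        ids = [f"x{i}" for i in range(30)]
        scores = {i: float(rng.integers(0, 5)) for i in ids}
        res = roc_auc(scores, set(ids[:10]), set(ids[10:]))
        fpr, tpr = zip(*res.curve)
        assert (fpr[0], tpr[0]) == (0.0, 0.0)
        assert (fpr[-1], tpr[-1]) == (1.0, 1.0)
        assert np.trapezoid(tpr, fpr) == pytest.approx(res.auc)

    def test_validation_errors(self):
        scores = {"a": 1.0, "b": 0.5}
        with pytest.raises(ValueError, match="nonempty"):
            roc_auc(scores, set(), {"b"})
        with pytest.raises(ValueError, match="overlap"):
            roc_auc(scores, {"a"}, {"a", "b"})


def chain_pipeline():
    """Tiny deterministic 2-disease problem on a 6-node network."""
    nodes = {
        "g1": "gene", "g2": "gene", "g3": "gene",
        "l1": "lncRNA", "l2": "lncRNA", "l3": "lncRNA",
    }
    edges = {
        ("g1", "g2"): 1.0, ("g2", "l1"): 0.5, ("g3", "l2"): 1.0,
        ("g1", "l3"): 0.25,
    }
    net = PanCancerNetwork(
        node_types=nodes,
        edges={tuple(sorted(k)): w for k, w in edges.items()},
        provenance={tuple(sorted(k)): (1, None) for k in edges},
    )
    P = PhenotypeSimilarityMatrix(
        P=pd.DataFrame(
            [[1.0, 0.5], [0.5, 1.0]], index=["D1", "D2"], columns=["D1", "D2"]
        )
    )
    seeds = {
        "D1": SeedSet("D1", frozenset({"g1", "g2"})),
        "D2": SeedSet("D2", frozenset({"g3"})),
    }
    return PrioritizationPipeline(network=net, seeds=seeds, phenotype=P)


def chain_evaluator(**kwargs):
    pipeline = chain_pipeline()
    config = EvaluationConfig(
        positives={"D1": {"l1"}, "D2": {"l2"}}, rng_seed=0, **kwargs
    )
    return Evaluator(pipeline, config)


class TestLoocv:
    def test_two_seeds_give_two_held_out_evaluations(self):
        ev = chain_evaluator()
        res = ev.loocv_genes("D1")
        assert set(res.held_out_ranks) == {"g1", "g2"}
        assert res.roc.n_pos == 2

    def test_single_seed_disease_skipped(self, caplog):
        ev = chain_evaluator()
        with caplog.at_level("WARNING"):
            assert ev.loocv_genes("D2") is None
        assert any("LOOCV skipped" in r.message for r in caplog.records)

    def test_sole_neighbor_held_out_seed_ranks_first(self):
        """If the held-out seed is the only neighbor of the remaining seed,
        propagation must put it at rank 1."""
        nodes = {"g1": "gene", "g2": "gene", "g3": "gene", "g4": "gene",
                 "l1": "lncRNA"}
        edges = {("g1", "g2"): 1.0, ("g3", "l1"): 1.0}
        net = PanCancerNetwork(
            node_types=nodes,
            edges={tuple(sorted(k)): w for k, w in edges.items()},
            provenance={tuple(sorted(k)): (1, None) for k in edges},
        )
        P = PhenotypeSimilarityMatrix(
            P=pd.DataFrame([[1.0]], index=["D1"], columns=["D1"])
        )
        pipeline = PrioritizationPipeline(
            network=net,
            seeds={"D1": SeedSet("D1", frozenset({"g1", "g2"}))},
            phenotype=P,
        )
        ev = Evaluator(
            pipeline, EvaluationConfig(positives={"D1": {"l1"}}, rng_seed=0)
        )
        res = ev.loocv_genes("D1")
        # holding out g2: the walk restarts at g1, whose only neighbor is g2
        assert res.held_out_ranks["g2"] == 1
        assert res.held_out_ranks["g1"] == 1

    def test_ranks_match_dense_solve_oracle(self, benchmark, bench_pipeline,
                                            bench_evaluator):
        """Held-out ranks agree with a from-scratch dense linear solve."""
        d = benchmark.spec.disease_ids[0]
        res = bench_evaluator.loocv_genes(d)
        tm = bench_pipeline.tm
        P = benchmark.phenotype.P
        seeds = benchmark.seeds[d].gene_ids
        gene_nodes = bench_pipeline.network.nodes_of_type("gene")
        negatives = sorted(set(gene_nodes) - set(seeds))
        S_base = bench_pipeline.prediction_scores()
        for g in sorted(seeds):
            p = dense_rwr_solve(tm, set(seeds) - {g}, 0.7)
            S = S_base.copy()
            S.loc[d] = p
            row = pd.Series(
                P.loc[d].to_numpy() @ S.to_numpy(), index=S.columns
            )
            ordered = sorted([g] + negatives, key=lambda n: (-row[n], n))
            assert res.held_out_ranks[g] == ordered.index(g) + 1


class TestAblatePhenotype:
    def test_exclude_equals_unintegrated_pipeline(self):
        ev = chain_evaluator()
        excl = ev.ablate_phenotype("exclude")
        S = ev.pipeline.prediction_scores()
        for d in ev.diseases:
            direct = roc_auc(
                S.loc[d],
                ev.config.positives[d],
                ev._lnc_negatives(d),
            ).auc
            assert excl.loc[0, d] == pytest.approx(direct)

    def test_two_disease_permutation_is_degenerate(self):
        """With one off-diagonal pair the symmetric shuffle is the identity."""
        ev = chain_evaluator()
        intact = ev.mean_auc()
        perm = ev.ablate_phenotype("permute", n_reps=5, rng_seed=1)
        assert np.allclose(perm.to_numpy().mean(axis=1), intact)

    def test_exchangeable_offdiagonals_reproduce_intact_auc(self, benchmark,
                                                            bench_pipeline):
        """A phenotype matrix with all off-diagonals equal is invariant
        under the symmetric-pair shuffle."""
        ids = benchmark.spec.disease_ids
        P = PhenotypeSimilarityMatrix(
            P=pd.DataFrame(
                np.full((len(ids), len(ids)), 0.4) + 0.6 * np.eye(len(ids)),
                index=ids, columns=ids,
            )
        )
        pipeline = PrioritizationPipeline(
            network=bench_pipeline.network, seeds=benchmark.seeds, phenotype=P
        )
        ev = Evaluator(
            pipeline, EvaluationConfig(positives=benchmark.positives, rng_seed=0)
        )
        intact = ev.mean_auc()
        perm = ev.ablate_phenotype("permute", n_reps=3, rng_seed=2)
        assert np.allclose(perm.to_numpy().mean(axis=1), intact)

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError, match="unknown ablation mode"):
            chain_evaluator().ablate_phenotype("scramble")


class TestRandomSeedControl:
    def test_benchmark_p_bounds_and_determinism(self, benchmark, bench_evaluator):
        pool = benchmark.truth["non_disease_pool"]
        r1 = bench_evaluator.random_seed_control(pool, n_reps=20, rng_seed=9)
        r2 = bench_evaluator.random_seed_control(pool, n_reps=20, rng_seed=9)
        assert np.array_equal(r1.aucs, r2.aucs)
        assert r1.p_value == r2.p_value
        assert 1 / 21 <= r1.p_value <= 1.0

    def test_pool_overlap_and_size_validation(self, benchmark, bench_evaluator):
        seeds = benchmark.truth["seeds"]["D1"]
        with pytest.raises(ValueError, match="overlap"):
            bench_evaluator.random_seed_control(
                benchmark.truth["non_disease_pool"] + seeds[:1], n_reps=1
            )
        with pytest.raises(ValueError, match="smaller"):
            bench_evaluator.random_seed_control(
                benchmark.truth["non_disease_pool"][:2], n_reps=1
            )


class TestSubsetDiseases:
    def test_full_size_equals_full_pipeline(self):
        ev = chain_evaluator()
        sweep = ev.subset_diseases([2], n_reps=3, rng_seed=4)
        assert sweep.mean_by_size[2] == pytest.approx(ev.mean_auc())

    def test_size_one_equals_exclude(self):
        ev = chain_evaluator()
        sweep = ev.subset_diseases([1], n_reps=2, rng_seed=5)
        excl = ev.ablate_phenotype("exclude")
        assert sweep.mean_by_size[1] == pytest.approx(float(excl.to_numpy().mean()))

    def test_invalid_sizes_rejected(self):
        ev = chain_evaluator()
        with pytest.raises(ValueError, match="< 1"):
            ev.subset_diseases([0], n_reps=1)
        with pytest.raises(ValueError, match="exceeds"):
            ev.subset_diseases([3], n_reps=1)

    def test_reproducible_given_seed(self):
        ev = chain_evaluator()
        a = ev.subset_diseases([1, 2], n_reps=3, rng_seed=6).per_rep
        b = ev.subset_diseases([1, 2], n_reps=3, rng_seed=6).per_rep
        pd.testing.assert_frame_equal(a, b)


def test_plot_roc_writes_figure(tmp_path):
    from lncprior.evaluate import plot_roc

    ev = chain_evaluator()
    out = tmp_path / "roc.png"
    plot_roc(ev.lncrna_roc(), out)
    assert out.stat().st_size > 0


class TestLeaveDiseaseOut:
    def make(self, sim):
        nodes = {"g1": "gene", "g2": "gene", "l1": "lncRNA", "l2": "lncRNA"}
        edges = {("g1", "l1"): 1.0, ("g2", "l2"): 1.0}
        net = PanCancerNetwork(
            node_types=nodes,
            edges={tuple(sorted(k)): w for k, w in edges.items()},
            provenance={tuple(sorted(k)): (1, None) for k in edges},
        )
        P = PhenotypeSimilarityMatrix(
            P=pd.DataFrame(
                [[1.0, sim], [sim, 1.0]], index=["D1", "D2"], columns=["D1", "D2"]
            )
        )
        seeds = {
            "D1": SeedSet("D1", frozenset({"g1"})),
            "D2": SeedSet("D2", frozenset({"g2"})),
        }
        pipeline = PrioritizationPipeline(network=net, seeds=seeds, phenotype=P)
        return Evaluator(
            pipeline,
            EvaluationConfig(positives={"D1": {"l1"}, "D2": {"l2"}}, rng_seed=0),
        )

    def test_zero_similarity_gives_all_tied_scores(self, caplog):
        ev = self.make(0.0)
        with caplog.at_level("WARNING"):
            res = ev.leave_disease_out("D1")
        assert res.auc == pytest.approx(0.5)  # all-zero scores: pure ties
        assert any("zero similarity" in r.message for r in caplog.records)

    def test_unit_similarity_transfers_other_disease_scores(self):
        ev = self.make(1.0)
        res = ev.leave_disease_out("D1")
        S = ev.pipeline.prediction_scores()
        direct = roc_auc(S.loc["D2"], {"l1"}, {"l2"}).auc
        assert res.auc == pytest.approx(direct)
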