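import numpy as np
import pytest

from lncprior.evaluate import EvaluationConfig, Evaluator
from lncprior.network import build_network
from lncprior.pipeline import PrioritizationPipeline
from lncprior.synthetic import (
    SyntheticSpec,
    generate_benchmark,
    generate_probe_fixture,
)


@pytest.fixture(scope="session")
def benchmark():
    """The default planted benchmark (6 diseases, 500 genes, 200 lncRNAs)."""
    return generate_benchmark(SyntheticSpec())


@pytest.fixture(scope="session")
def bench_pipeline(benchmark):
    net = build_network(
        [benchmark.expression[d] for d in benchmark.spec.disease_ids],
        benchmark.ppi,
    )
    return PrioritizationPipeline(
        network=net, seeds=benchmark.seeds, phenotype=benchmark.phenotype
    )


@pytest.fixture(scope="session")
def bench_evaluator(benchmark, bench_pipeline):
    return Evaluator(
        bench_pipeline,
        EvaluationConfig(positives=benchmark.positives, rng_seed=0),
    )


@pytest.fixture(scope="session")
def small_spec():
    """A fast benchmark variant for CLI / determinism round trips."""
    return SyntheticSpec(
        n_diseases=4,
        n_genes=60,
        n_lncrnas=30,
        samples_per_disease=30,
        n_modules=4,
        module_size=12,
        seeds_per_disease=3,
        planted_lnc_per_disease=4,
        rng_seed=7,
    )


@pytest.fixture(scope="session")
def probe_fixture():
    return generate_probe_fixture()


def dense_rwr_solve(tm, seeds, restart):
    """Closed-form RWR oracle: p = r (I - (1-r) W)^-1 p0, dense solve.

    Dangling columns are redirected to the restart vector, matching the
    iterative scheme's mass conservation.
    """
    n = tm.n_nodes
    W = tm.W.toarray()
    seeds = sorted(set(seeds))
    p0 = np.zeros(n)
    p0[[tm.index[s] for s in seeds]] = 1.0 / len(seeds)
    Wt = W + np.outer(p0, tm.dangling.astype(float))
    return restart * np.linalg.solve(np.eye(n) - (1 - restart) * Wt, p0)
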