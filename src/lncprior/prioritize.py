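"""Random walk with restart and phenotype-similarity integration.

Known disease genes seed a random walk with restart (RWR) on the weighted
pan-cancer network: p <- (1-r)·W·p + r·p0, with W the column-normalized
weighted adjacency and p0 uniform over the seed set.  The converged
steady-state p scores every node's network proximity to the seeds.  Per-
disease score rows are then pooled across diseases through a phenotype-
similarity matrix P:

    s_ik = sum_j P_ij · s_jk

so a disease borrows evidence from phenotypically similar diseases.
Candidates are ranked by the integrated score, descending, ties broken by
node id.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .network import GENE, LNCRNA, PanCancerNetwork

DEFAULT_RESTART = 0.7
DEFAULT_TOL = 1e-10
DEFAULT_MAX_ITER = 1000

__all__ = [
    "SeedSet",
    "PhenotypeSimilarityMatrix",
    "TransitionMatrix",
    "PrioritizationResult",
    "ConvergenceError",
    "transition_matrix",
    "rwr",
    "integrate_phenotype",
    "rank_candidates",
    "read_seeds",
    "read_phenotype_matrix",
    "DEFAULT_RESTART",
]


class ConvergenceError(RuntimeError):
    """Raised when RWR power iteration fails to reach tolerance."""


@dataclass(frozen=True)
class SeedSet:
    """Known disease genes used as the restart set for one disease."""

    disease_id: str
    gene_ids: frozenset[str]

    def __post_init__(self) -> None:
        if not self.gene_ids:
            raise ValueError(f"no seeds for disease {self.disease_id!r}")


@dataclass
class PhenotypeSimilarityMatrix:
    """Symmetric disease x disease similarity scores in [0, 1], diagonal 1."""

    P: pd.DataFrame

    def __post_init__(self) -> None:
        P = self.P
        if list(P.index) != list(P.columns):
            raise ValueError("phenotype matrix index and columns differ")
        vals = P.to_numpy(dtype=float)
        if not np.allclose(vals, vals.T):
            raise ValueError("phenotype matrix is not symmetric")
        if vals.min() < 0 or vals.max() > 1:
            raise ValueError("phenotype similarities must lie in [0, 1]")
        self.P = P.astype(float)

    @property
    def diseases(self) -> list[str]:
        return list(self.P.index)

    def to_numpy(self) -> np.ndarray:
        return self.P.to_numpy()


@dataclass
class TransitionMatrix:
    """Column-stochastic walk operator over a fixed node ordering.

    ``W[u, v]`` is the probability of stepping u <- v, i.e. edge weight
    (u, v) over the total weight incident to v.  Columns of isolated nodes
    are all-zero and flagged in ``dangling``; the walk redistributes their
    mass to the restart vector.
    """

    W: sp.csr_matrix
    node_ids: list[str]
    dangling: np.ndarray
    index: dict[str, int] = field(init=False)

    def __post_init__(self) -> None:
        self.index = {n: i for i, n in enumerate(self.node_ids)}

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)


def transition_matrix(net: PanCancerNetwork) -> TransitionMatrix:
    """Column-normalize the weighted adjacency of the network.

    Node ordering is sorted node id, making every downstream score vector
    deterministic regardless of construction order.
    """
    if net.n_nodes == 0:
        raise ValueError("network is empty")
    node_ids = sorted(net.node_types)
    index = {n: i for i, n in enumerate(node_ids)}
    n = len(node_ids)
    if net.edges:
        rows, cols, vals = [], [], []
        for (a, b), w in net.edges.items():
            ia, ib = index[a], index[b]
            rows += [ia, ib]
            cols += [ib, ia]
            vals += [w, w]
        adj = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsc()
    else:
        adj = sp.csc_matrix((n, n))
    colsum = np.asarray(adj.sum(axis=0)).ravel()
    dangling = colsum == 0
    scale = np.where(dangling, 1.0, colsum)
    W = (adj @ sp.diags(1.0 / scale)).tocsr()
    return TransitionMatrix(W=W, node_ids=node_ids, dangling=dangling)


def _restart_vector(tm: TransitionMatrix, seeds: Iterable[str]) -> np.ndarray:
    seed_list = sorted(set(seeds))
    if not seed_list:
        raise ValueError("no seeds for disease")
    missing = [s for s in seed_list if s not in tm.index]
    if missing:
        raise ValueError(f"seed nodes absent from network: {missing[:5]}")
    p0 = np.zeros(tm.n_nodes)
    p0[[tm.index[s] for s in seed_list]] = 1.0 / len(seed_list)
    return p0


def rwr(
    tm: TransitionMatrix,
    seeds: SeedSet | Iterable[str],
    restart: float = DEFAULT_RESTART,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> np.ndarray:
    """Random walk with restart; returns the steady-state score vector.

    Iterates p <- (1-r)·(W·p + m·p0) + r·p0 where m is the probability mass
    sitting on dangling (isolated) columns, so the total mass stays 1.
    Converged when the L1 change drops below ``tol``.
    """
    if not 0 < restart < 1:
        raise ValueError(f"restart must lie in (0, 1), got {restart}")
    seed_ids = seeds.gene_ids if isinstance(seeds, SeedSet) else seeds
    p0 = _restart_vector(tm, seed_ids)
    p = p0.copy()
    for _ in range(max_iter):
        dangling_mass = p[tm.dangling].sum() if tm.dangling.any() else 0.0
        p_next = (1 - restart) * (tm.W @ p + dangling_mass * p0) + restart * p0
        delta = np.abs(p_next - p).sum()
        p = p_next
        if delta < tol:
            return p
    raise ConvergenceError(
        f"RWR did not converge in {max_iter} iterations (last L1 residual {delta:.3e})"
    )


@dataclass
class PrioritizationResult:
    """Integrated disease x node score matrix plus node-type labels."""

    integrated: pd.DataFrame
    node_types: Mapping[str, str]

    @property
    def diseases(self) -> list[str]:
        return list(self.integrated.index)


def integrate_phenotype(
    S: pd.DataFrame,
    phenotype: PhenotypeSimilarityMatrix,
    node_types: Mapping[str, str],
) -> PrioritizationResult:
    """Pool per-disease prediction scores through phenotype similarity.

    ``S`` rows are per-disease RWR score vectors in the same disease order
    as the phenotype matrix; returns s_ik = sum_j P_ij·s_jk (j = i
    included).
    """
    if list(S.index) != phenotype.diseases:
        raise ValueError(
            "disease ordering of prediction scores and phenotype matrix differ"
        )
    integrated = pd.DataFrame(
        phenotype.to_numpy() @ S.to_numpy(),
        index=S.index,
        columns=S.columns,
    )
    return PrioritizationResult(integrated=integrated, node_types=node_types)


def rank_candidates(
    result: PrioritizationResult,
    disease_id: str,
    node_type: str,
    exclude: Iterable[str] = (),
) -> pd.DataFrame:
    """Rank nodes of one type for one disease, descending by score.

    Ties are broken by node id (lexicographic), so rankings are
    deterministic across runs.  Returns columns (rank, node_id, node_type,
    score).
    """
    if disease_id not in result.integrated.index:
        raise ValueError(f"unknown disease_id {disease_id!r}")
    if node_type not in (GENE, LNCRNA):
        raise ValueError(f"unknown node type {node_type!r}")
    excluded = set(exclude)
    row = result.integrated.loc[disease_id]
    nodes = [
        n for n in row.index if result.node_types[n] == node_type and n not in excluded
    ]
    ordered = sorted(nodes, key=lambda n: (-row[n], n))
    return pd.DataFrame(
        {
            "rank": np.arange(1, len(ordered) + 1),
            "node_id": ordered,
            "node_type": node_type,
            "score": [row[n] for n in ordered],
        }
    )


# ---------------------------------------------------------------------------
# readers


def read_seeds(path: str | Path) -> dict[str, SeedSet]:
    """Read a 2-column TSV (disease_id, gene_id) into per-disease seed sets."""
    df = pd.read_csv(path, sep="\t", header=None, names=["disease_id", "gene_id"])
    out: dict[str, set[str]] = {}
    for d, g in zip(df["disease_id"].astype(str), df["gene_id"].astype(str)):
        out.setdefault(d, set()).add(g)
    return {d: SeedSet(d, frozenset(gs)) for d, gs in sorted(out.items())}


def read_phenotype_matrix(path: str | Path) -> PhenotypeSimilarityMatrix:
    """Read a disease x disease similarity TSV; absent diagonal entries are
    set to 1 (self-similarity maximal)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    vals = df.to_numpy(dtype=float)
    np.fill_diagonal(vals, 1.0)
    return PhenotypeSimilarityMatrix(
        P=pd.DataFrame(
            vals, index=df.index.astype(str), columns=df.columns.astype(str)
        )
    )
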