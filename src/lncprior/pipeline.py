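"""End-to-end prioritization context: network + seeds + phenotype matrix.

Caches the transition operator and the per-disease RWR score rows so the
evaluation protocols (LOOCV, seed randomization, phenotype ablations) can
recompute only the rows a perturbation actually touches.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .network import PanCancerNetwork
from .prioritize import (
    DEFAULT_MAX_ITER,
    DEFAULT_RESTART,
    DEFAULT_TOL,
    PhenotypeSimilarityMatrix,
    PrioritizationResult,
    SeedSet,
    TransitionMatrix,
    integrate_phenotype,
    rwr,
    transition_matrix,
)

__all__ = ["PrioritizationPipeline"]


@dataclass
class PrioritizationPipeline:
    """Holds one prioritization problem and computes its score matrices.

    ``seeds`` must cover every disease in the phenotype matrix; each seed
    id must be a gene-type node of the network.
    """

    network: PanCancerNetwork
    seeds: Mapping[str, SeedSet]
    phenotype: PhenotypeSimilarityMatrix
    restart: float = DEFAULT_RESTART
    tol: float = DEFAULT_TOL
    max_iter: int = DEFAULT_MAX_ITER
    _tm: TransitionMatrix | None = field(default=None, repr=False)
    _S: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        missing = [d for d in self.phenotype.diseases if d not in self.seeds]
        if missing:
            raise ValueError(f"diseases without seed sets: {missing}")
        for d in self.phenotype.diseases:
            for g in self.seeds[d].gene_ids:
                t = self.network.node_types.get(g)
                if t is None:
                    raise ValueError(f"seed {g!r} ({d}) absent from network")
                if t != "gene":
                    raise ValueError(f"seed {g!r} ({d}) is not a gene-type node")

    @property
    def diseases(self) -> list[str]:
        return self.phenotype.diseases

    @property
    def tm(self) -> TransitionMatrix:
        if self._tm is None:
            self._tm = transition_matrix(self.network)
        return self._tm

    def _walk(self, seed_ids: Iterable[str]) -> np.ndarray:
        return rwr(
            self.tm,
            seed_ids,
            restart=self.restart,
            tol=self.tol,
            max_iter=self.max_iter,
        )

    def prediction_scores(
        self, seeds_override: Mapping[str, Iterable[str]] | None = None
    ) -> pd.DataFrame:
        """Per-disease RWR score rows (diseases x nodes, rows sum to 1).

        ``seeds_override`` replaces individual diseases' seed sets; rows for
        unchanged diseases are reused from cache.
        """
        base = self._base_scores()
        if not seeds_override:
            return base.copy()
        S = base.copy()
        for d, ids in seeds_override.items():
            if d not in S.index:
                raise ValueError(f"unknown disease_id {d!r}")
            S.loc[d] = self._walk(ids)
        return S

    def _base_scores(self) -> pd.DataFrame:
        if self._S is None:
            rows = [self._walk(self.seeds[d].gene_ids) for d in self.diseases]
            self._S = pd.DataFrame(
                np.vstack(rows), index=self.diseases, columns=self.tm.node_ids
            )
        return self._S

    def integrate(
        self,
        S: pd.DataFrame | None = None,
        phenotype: PhenotypeSimilarityMatrix | None = None,
    ) -> PrioritizationResult:
        return integrate_phenotype(
            self.prediction_scores() if S is None else S,
            self.phenotype if phenotype is None else phenotype,
            self.network.node_types,
        )

    def run(self) -> PrioritizationResult:
        """Full pipeline: walks for every disease, then phenotype pooling."""
        return self.integrate()
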