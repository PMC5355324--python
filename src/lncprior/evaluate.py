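"""Evaluation protocols for the prioritization pipeline.

Implements ROC/AUC against known disease lncRNAs, gene leave-one-out
cross-validation (LOOCV), and the robustness/importance analyses: removing
or permuting the phenotype-similarity matrix, replacing the known disease
genes with random non-disease genes, restricting integration to random
disease subsets, and leave-disease-out prediction.

AUC is the Mann-Whitney rank statistic: the probability that a random
positive outscores a random negative, with ties credited 1/2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.metrics import roc_curve as _sk_roc_curve

from .network import GENE, LNCRNA
from .pipeline import PrioritizationPipeline
from .prioritize import PhenotypeSimilarityMatrix, PrioritizationResult

logger = logging.getLogger(__name__)

__all__ = [
    "EvaluationConfig",
    "RocResult",
    "LoocvResult",
    "RandomSeedControlResult",
    "SubsetSweepResult",
    "roc_auc",
    "Evaluator",
]


@dataclass
class RocResult:
    """ROC curve and area for one disease's candidate ranking."""

    disease_id: str
    auc: float
    curve: list[tuple[float, float]]
    n_pos: int
    n_neg: int


@dataclass
class EvaluationConfig:
    """Known positives and Monte-Carlo settings for the evaluation suite."""

    positives: Mapping[str, set[str]]
    n_permutations: int = 1000
    rng_seed: int = 0
    subset_sizes: Sequence[int] = (3, 6, 9, 12)

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        empty = [d for d, p in self.positives.items() if not p]
        if empty:
            raise ValueError(f"empty positive sets for diseases: {empty}")


def roc_auc(
    scores: Mapping[str, float] | pd.Series,
    positives: Iterable[str],
    negatives: Iterable[str],
    disease_id: str = "",
) -> RocResult:
    """Rank-statistic AUC plus the ROC curve.

    AUC = U / (n_pos * n_neg) where U counts positive-over-negative score
    pairs, ties counted 1/2.  The curve is computed on the same scores and
    its trapezoidal area equals the rank AUC.
    """
    pos = sorted(set(positives))
    neg = sorted(set(negatives))
    if not pos or not neg:
        raise ValueError("positives and negatives must both be nonempty")
    overlap = set(pos) & set(neg)
    if overlap:
        raise ValueError(f"positives and negatives overlap: {sorted(overlap)[:5]}")
    if isinstance(scores, pd.Series):
        scores = scores.to_dict()
    s = np.array([scores[n] for n in pos + neg], dtype=float)
    n_pos, n_neg = len(pos), len(neg)
    ranks = rankdata(s)
    u = ranks[:n_pos].sum() - n_pos * (n_pos + 1) / 2
    auc = u / (n_pos * n_neg)
    y = np.concatenate([np.ones(n_pos), np.zeros(n_neg)])
    fpr, tpr, _ = _sk_roc_curve(y, s, drop_intermediate=False)
    return RocResult(
        disease_id=disease_id,
        auc=float(auc),
        curve=list(zip(fpr.tolist(), tpr.tolist())),
        n_pos=n_pos,
        n_neg=n_neg,
    )


def _rank_step_curve(a_values: np.ndarray, n_pos: int, n_neg: int) -> list[tuple[float, float]]:
    """Exact ROC step curve from per-positive counts of outranking negatives.

    ``a_values[g]`` is the number of negatives scoring >= positive g (half
    counts from score ties allowed).  Jump points are duplicated so the
    trapezoidal area equals sum(n_neg - a_g) / (n_pos * n_neg) exactly.
    """
    pts: list[tuple[float, float]] = [(0.0, 0.0)]
    tpr = 0.0
    for tau in np.unique(a_values):
        x = float(tau) / n_neg
        pts.append((x, tpr))
        tpr = float((a_values <= tau).sum()) / n_pos
        pts.append((x, tpr))
    pts.append((1.0, tpr))
    return pts


@dataclass
class LoocvResult:
    """Held-out seed-gene ranks and the pooled cross-validation ROC."""

    disease_id: str
    held_out_ranks: dict[str, int]
    n_candidates: int
    roc: RocResult


@dataclass
class RandomSeedControlResult:
    """Null AUC distribution from random non-disease seed genes."""

    aucs: np.ndarray
    true_auc: float
    p_value: float


@dataclass
class SubsetSweepResult:
    """Mean AUC as a function of the number of integrated diseases."""

    per_rep: pd.DataFrame  # columns: size, rep, mean_auc
    mean_by_size: dict[int, float]


def plot_roc(rocs: Mapping[str, RocResult], path) -> None:
    """Write a ROC-curve figure (one curve per disease) to ``path``."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    for d, r in sorted(rocs.items()):
        fpr, tpr = zip(*r.curve)
        ax.plot(fpr, tpr, label=f"{d} (AUC {r.auc:.3f})")
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


class Evaluator:
    """Runs the evaluation protocols against one prioritization pipeline."""

    def __init__(self, pipeline: PrioritizationPipeline, config: EvaluationConfig):
        self.pipeline = pipeline
        self.config = config
        self.diseases = [
            d for d in pipeline.diseases if config.positives.get(d)
        ]
        if not self.diseases:
            raise ValueError("no disease has a nonempty positive set")

    # -- plain ROC ---------------------------------------------------------

    def _lnc_negatives(self, disease_id: str) -> list[str]:
        lnc = self.pipeline.network.nodes_of_type(LNCRNA)
        return sorted(set(lnc) - set(self.config.positives[disease_id]))

    def _disease_roc(
        self, result: PrioritizationResult, disease_id: str
    ) -> RocResult:
        row = result.integrated.loc[disease_id]
        return roc_auc(
            row,
            self.config.positives[disease_id],
            self._lnc_negatives(disease_id),
            disease_id=disease_id,
        )

    def lncrna_roc(
        self, result: PrioritizationResult | None = None
    ) -> dict[str, RocResult]:
        """Per-disease ROC of the integrated scores against known lncRNAs.

        Negatives are all lncRNA-type nodes not in the disease's positive
        list.
        """
        if result is None:
            result = self.pipeline.run()
        return {d: self._disease_roc(result, d) for d in self.diseases}

    def mean_auc(self, rocs: Mapping[str, RocResult] | None = None) -> float:
        """Unweighted arithmetic mean AUC across evaluated diseases."""
        if rocs is None:
            rocs = self.lncrna_roc()
        return float(np.mean([r.auc for r in rocs.values()]))

    # -- gene LOOCV --------------------------------------------------------

    def loocv_genes(self, disease_id: str) -> LoocvResult | None:
        """Leave-one-out cross-validation of the disease's seed genes.

        Each seed is withheld in turn, the withheld disease's walk and the
        cross-disease integration are honestly recomputed, and the held-out
        gene's rank among gene-type non-seed nodes is recorded.  The AUC
        pools, per held-out gene, its pairwise comparisons against the
        never-seed genes of its own re-run.  Diseases with fewer than two
        seeds are skipped (a single seed leaves nothing to walk from).
        """
        seeds = self.pipeline.seeds[disease_id].gene_ids
        if len(seeds) < 2:
            logger.warning(
                "LOOCV skipped for %s: only %d known disease gene(s)",
                disease_id,
                len(seeds),
            )
            return None
        gene_nodes = self.pipeline.network.nodes_of_type(GENE)
        negatives = sorted(set(gene_nodes) - set(seeds))
        n_neg = len(negatives)
        ranks: dict[str, int] = {}
        a_values = []
        for g in sorted(seeds):
            remaining = set(seeds) - {g}
            S = self.pipeline.prediction_scores({disease_id: remaining})
            result = self.pipeline.integrate(S)
            row = result.integrated.loc[disease_id]
            candidates = [g] + negatives
            ordered = sorted(candidates, key=lambda n: (-row[n], n))
            ranks[g] = ordered.index(g) + 1
            sg = row[g]
            neg_scores = row[negatives].to_numpy()
            a_values.append(
                float((neg_scores > sg).sum()) + 0.5 * float((neg_scores == sg).sum())
            )
        a = np.array(a_values)
        auc = float((n_neg - a).sum() / (len(seeds) * n_neg))
        roc = RocResult(
            disease_id=disease_id,
            auc=auc,
            curve=_rank_step_curve(a, len(seeds), n_neg),
            n_pos=len(seeds),
            n_neg=n_neg,
        )
        return LoocvResult(
            disease_id=disease_id,
            held_out_ranks=ranks,
            n_candidates=1 + n_neg,
            roc=roc,
        )

    # -- phenotype ablations ----------------------------------------------

    def _identity_phenotype(self) -> PhenotypeSimilarityMatrix:
        d = self.pipeline.diseases
        return PhenotypeSimilarityMatrix(
            P=pd.DataFrame(np.eye(len(d)), index=d, columns=d)
        )

    @staticmethod
    def permute_phenotype(
        phenotype: PhenotypeSimilarityMatrix, rng: np.random.Generator
    ) -> PhenotypeSimilarityMatrix:
        """Shuffle the off-diagonal entries over symmetric positions,
        preserving symmetry and the (unit) diagonal."""
        P = phenotype.to_numpy().copy()
        n = P.shape[0]
        iu = np.triu_indices(n, k=1)
        vals = rng.permutation(P[iu])
        P[iu] = vals
        P[(iu[1], iu[0])] = vals
        return PhenotypeSimilarityMatrix(
            P=pd.DataFrame(P, index=phenotype.diseases, columns=phenotype.diseases)
        )

    def ablate_phenotype(
        self,
        mode: str,
        n_reps: int = 1,
        rng_seed: int | None = None,
    ) -> pd.DataFrame:
        """Re-integrate with the phenotype matrix removed or permuted.

        ``mode="exclude"`` replaces P by the identity (no cross-disease
        pooling); ``mode="permute"`` shuffles the symmetric off-diagonal
        pairs ``n_reps`` times.  Returns a rep x disease AUC table; the
        walks themselves are unchanged, only the integration step reruns.
        """
        S = self.pipeline.prediction_scores()
        if mode == "exclude":
            result = self.pipeline.integrate(S, self._identity_phenotype())
            rows = [{d: self._disease_roc(result, d).auc for d in self.diseases}]
        elif mode == "permute":
            rng = np.random.default_rng(
                self.config.rng_seed if rng_seed is None else rng_seed
            )
            rows = []
            for _ in range(n_reps):
                perm = self.permute_phenotype(self.pipeline.phenotype, rng)
                result = self.pipeline.integrate(S, perm)
                rows.append({d: self._disease_roc(result, d).auc for d in self.diseases})
        else:
            raise ValueError(f"unknown ablation mode {mode!r}")
        out = pd.DataFrame(rows)
        out.index.name = "rep"
        return out

    # -- random non-disease seed control -----------------------------------

    def random_seed_control(
        self,
        non_disease_pool: Iterable[str],
        n_reps: int = 1000,
        rng_seed: int | None = None,
    ) -> RandomSeedControlResult:
        """Replace every disease's seeds with equal-size random draws from a
        non-disease gene pool and rebuild the null distribution of the mean
        AUC.  Empirical p = (#{null >= true} + 1) / (n_reps + 1)."""
        pool = sorted(set(non_disease_pool))
        all_seeds = set().union(
            *(self.pipeline.seeds[d].gene_ids for d in self.pipeline.diseases)
        )
        if set(pool) & all_seeds:
            raise ValueError("non-disease pool overlaps the true seed sets")
        max_seeds = max(
            len(self.pipeline.seeds[d].gene_ids) for d in self.pipeline.diseases
        )
        if len(pool) < max_seeds:
            raise ValueError(
                f"pool of {len(pool)} genes is smaller than the largest "
                f"seed set ({max_seeds})"
            )
        rng = np.random.default_rng(
            self.config.rng_seed if rng_seed is None else rng_seed
        )
        true_auc = self.mean_auc()
        aucs = np.empty(n_reps)
        pool_arr = np.array(pool)
        for rep in range(n_reps):
            override = {
                d: set(
                    rng.choice(
                        pool_arr,
                        size=len(self.pipeline.seeds[d].gene_ids),
                        replace=False,
                    )
                )
                for d in self.pipeline.diseases
            }
            S = self.pipeline.prediction_scores(override)
            result = self.pipeline.integrate(S)
            aucs[rep] = np.mean(
                [self._disease_roc(result, d).auc for d in self.diseases]
            )
        p = (float((aucs >= true_auc).sum()) + 1.0) / (n_reps + 1.0)
        return RandomSeedControlResult(aucs=aucs, true_auc=true_auc, p_value=p)

    # -- disease-subset sweep ----------------------------------------------

    def subset_diseases(
        self,
        sizes: Sequence[int] | None = None,
        n_reps: int = 10,
        rng_seed: int | None = None,
    ) -> SubsetSweepResult:
        """Integrate over random disease subsets of the given sizes.

        Each evaluated disease is always inside its own subset; its
        integrated row becomes sum over the subset of P_ij * s_j.  Walks
        are reused, only integration reruns.  Reports the per-rep mean AUC
        and its average per size.
        """
        if sizes is None:
            sizes = self.config.subset_sizes
        all_d = self.pipeline.diseases
        for size in sizes:
            if size < 1:
                raise ValueError(f"subset size {size} < 1")
            if size > len(all_d):
                raise ValueError(f"subset size {size} exceeds {len(all_d)} diseases")
        rng = np.random.default_rng(
            self.config.rng_seed if rng_seed is None else rng_seed
        )
        S = self.pipeline.prediction_scores()
        P = self.pipeline.phenotype.P
        records = []
        for size in sizes:
            for rep in range(n_reps):
                disease_aucs = []
                for d in self.diseases:
                    others = np.array([x for x in all_d if x != d])
                    chosen = rng.choice(others, size=size - 1, replace=False)
                    subset = [d] + chosen.tolist()
                    row = P.loc[d, subset].to_numpy() @ S.loc[subset].to_numpy()
                    scores = pd.Series(row, index=S.columns)
                    disease_aucs.append(
                        roc_auc(
                            scores,
                            self.config.positives[d],
                            self._lnc_negatives(d),
                            disease_id=d,
                        ).auc
                    )
                records.append(
                    {"size": size, "rep": rep, "mean_auc": float(np.mean(disease_aucs))}
                )
        per_rep = pd.DataFrame(records)
        mean_by_size = {
            int(s): float(g["mean_auc"].mean()) for s, g in per_rep.groupby("size")
        }
        return SubsetSweepResult(per_rep=per_rep, mean_by_size=mean_by_size)

    # -- leave-disease-out prediction ---------------------------------------

    def leave_disease_out(self, disease_id: str) -> RocResult:
        """Score a disease's candidates using only the other diseases.

        s_ik = sum over j != i of P_ij * s_jk; the disease's own prediction
        row is excluded, so performance reflects pure cross-disease
        transfer through phenotype similarity.
        """
        if disease_id not in self.diseases:
            raise ValueError(f"unknown or positive-less disease {disease_id!r}")
        if len(self.pipeline.diseases) < 2:
            raise ValueError("leave-disease-out needs >= 2 diseases")
        S = self.pipeline.prediction_scores()
        P = self.pipeline.phenotype.P
        others = [d for d in self.pipeline.diseases if d != disease_id]
        weights = P.loc[disease_id, others].to_numpy()
        if np.all(weights == 0):
            logger.warning(
                "%s has zero similarity to every other disease; scores are all zero",
                disease_id,
            )
        row = weights @ S.loc[others].to_numpy()
        scores = pd.Series(row, index=S.columns)
        return roc_auc(
            scores,
            self.config.positives[disease_id],
            self._lnc_negatives(disease_id),
            disease_id=disease_id,
        )
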