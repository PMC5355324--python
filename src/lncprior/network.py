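"""Gene–lncRNA co-expression pan-cancer network construction.

Per disease, all gene–gene and gene–lncRNA Pearson correlations are
thresholded (strictly greater than 0.8 and 0.7 respectively, on |r| by
default) to form a disease-specific co-expression edge set.  The
disease-specific sets are integrated into one pan-cancer network whose edge
weights are occurrence frequencies across disease types (k of n diseases ->
weight k/n), and protein–protein interactions with normalized probability
scores are merged in, taking the max where both sources cover a pair.
lncRNA–lncRNA pairs are never edges.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

GENE = "gene"
LNCRNA = "lncRNA"

GG_THRESHOLD = 0.8
GL_THRESHOLD = 0.7

__all__ = [
    "ExpressionMatrix",
    "CoexpressionEdgeSet",
    "PanCancerNetwork",
    "compute_coexpression",
    "integrate_pan_cancer",
    "merge_ppi",
    "read_expression_tsv",
    "read_node_types",
    "read_ppi_tsv",
    "write_network",
    "read_network",
    "GG_THRESHOLD",
    "GL_THRESHOLD",
]


def _edge_key(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


@dataclass
class ExpressionMatrix:
    """One disease's log2 feature x sample expression with node-type labels."""

    values: pd.DataFrame
    node_types: Mapping[str, str]
    disease_id: str

    def __post_init__(self) -> None:
        idx = self.values.index
        if idx.has_duplicates:
            dup = idx[idx.duplicated()][0]
            raise ValueError(f"{self.disease_id}: duplicate feature id {dup!r}")
        if self.values.shape[1] < 2:
            raise ValueError(
                f"{self.disease_id}: need >=2 samples for correlation, "
                f"got {self.values.shape[1]}"
            )
        missing = [f for f in idx if f not in self.node_types]
        if missing:
            raise ValueError(
                f"{self.disease_id}: features without node type: {missing[:5]}"
            )
        bad = {t for f in idx if (t := self.node_types[f]) not in (GENE, LNCRNA)}
        if bad:
            raise ValueError(f"{self.disease_id}: invalid node types {bad}")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


@dataclass
class CoexpressionEdgeSet:
    """Thresholded co-expression pairs for one disease.

    ``nodes`` carries every feature of the source expression matrix (with
    its type), so downstream ranking can include unconnected candidates.
    """

    disease_id: str
    edges: set[tuple[str, str]]
    nodes: dict[str, str]

    def __post_init__(self) -> None:
        for a, b in self.edges:
            if a == b:
                raise ValueError(f"{self.disease_id}: self-loop on {a!r}")
            if self.nodes.get(a) == LNCRNA and self.nodes.get(b) == LNCRNA:
                raise ValueError(f"{self.disease_id}: lncRNA–lncRNA edge ({a}, {b})")


@dataclass
class PanCancerNetwork:
    """Undirected weighted heterogeneous gene/lncRNA network.

    ``provenance`` records, per edge, in how many disease networks the pair
    co-expressed and (if merged) its PPI score.
    """

    node_types: dict[str, str]
    edges: dict[tuple[str, str], float] = field(default_factory=dict)
    provenance: dict[tuple[str, str], tuple[int, float | None]] = field(
        default_factory=dict
    )

    def __post_init__(self) -> None:
        for (a, b), w in self.edges.items():
            if a == b:
                raise ValueError(f"self-loop on {a!r}")
            if not 0 < w <= 1:
                raise ValueError(f"edge ({a}, {b}) weight {w} outside (0, 1]")

    @property
    def n_nodes(self) -> int:
        return len(self.node_types)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def weight(self, a: str, b: str) -> float | None:
        return self.edges.get(_edge_key(a, b))

    def nodes_of_type(self, node_type: str) -> list[str]:
        return sorted(n for n, t in self.node_types.items() if t == node_type)


def _standardize_rows(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Return z-scored rows (ddof=1) and a validity mask (nonzero variance)."""
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    valid = (sd > 0).ravel()
    sd_safe = np.where(sd > 0, sd, 1.0)
    return (x - mu) / sd_safe, valid


def compute_coexpression(
    expr: ExpressionMatrix,
    gg_threshold: float = GG_THRESHOLD,
    gl_threshold: float = GL_THRESHOLD,
    *,
    signed: bool = False,
    block_size: int = 2000,
) -> CoexpressionEdgeSet:
    """Threshold all gene–gene and gene–lncRNA Pearson correlations.

    The co-expression score is |r| by default (``signed=True`` uses raw r).
    A pair is an edge iff its score strictly exceeds its kind's threshold.
    Zero-variance features are skipped with a warning (correlation
    undefined).  Correlations are computed blockwise; the result does not
    depend on ``block_size``.
    """
    if not 0 < gg_threshold < 1 or not 0 < gl_threshold < 1:
        raise ValueError("thresholds must lie in (0, 1)")
    x = expr.values.to_numpy(dtype=float)
    ids = np.asarray(expr.feature_ids)
    n = x.shape[1]
    if n < 3:
        logger.warning(
            "%s: only %d samples; correlations will be degenerate", expr.disease_id, n
        )
    z, valid = _standardize_rows(x)
    if not valid.all():
        for f in ids[~valid]:
            logger.warning(
                "%s: feature %s has zero variance; its pairs are skipped",
                expr.disease_id,
                f,
            )
    is_lnc = np.array([expr.node_types[f] == LNCRNA for f in ids])

    edges: set[tuple[str, str]] = set()
    n_feat = len(ids)
    for lo in range(0, n_feat, block_size):
        hi = min(lo + block_size, n_feat)
        corr = z[lo:hi] @ z.T / (n - 1)
        score = corr if signed else np.abs(corr)
        block_lnc = is_lnc[lo:hi, None]
        both_gene = ~block_lnc & ~is_lnc[None, :]
        forbidden = block_lnc & is_lnc[None, :]
        thresh = np.where(both_gene, gg_threshold, gl_threshold)
        hit = (score > thresh) & ~forbidden
        hit &= valid[lo:hi, None] & valid[None, :]
        # upper triangle only (global indices), no self pairs
        rows, cols = np.nonzero(hit)
        rows_g = rows + lo
        keep = rows_g < cols
        for i, j in zip(rows_g[keep], cols[keep]):
            edges.add(_edge_key(ids[i], ids[j]))

    return CoexpressionEdgeSet(
        disease_id=expr.disease_id,
        edges=edges,
        nodes={f: expr.node_types[f] for f in ids},
    )


def integrate_pan_cancer(
    edge_sets: Sequence[CoexpressionEdgeSet],
    n_diseases: int | None = None,
) -> PanCancerNetwork:
    """Union disease-specific edge sets; weight = occurrence frequency k/n."""
    if not edge_sets:
        raise ValueError("no edge sets to integrate")
    ids = [es.disease_id for es in edge_sets]
    if len(set(ids)) != len(ids):
        dup = next(d for d in ids if ids.count(d) > 1)
        raise ValueError(f"duplicate disease_id {dup!r}")
    n = n_diseases if n_diseases is not None else len(edge_sets)
    if n < 1 or n < len(edge_sets):
        raise ValueError(f"n_diseases={n} inconsistent with {len(edge_sets)} edge sets")

    node_types: dict[str, str] = {}
    for es in edge_sets:
        for node, t in es.nodes.items():
            if node_types.setdefault(node, t) != t:
                raise ValueError(f"node {node!r} has conflicting types across diseases")

    counts: dict[tuple[str, str], int] = {}
    for es in edge_sets:
        for key in es.edges:
            counts[key] = counts.get(key, 0) + 1

    edges = {key: c / n for key, c in counts.items()}
    provenance = {key: (c, None) for key, c in counts.items()}
    return PanCancerNetwork(node_types=node_types, edges=edges, provenance=provenance)


def merge_ppi(
    net: PanCancerNetwork,
    ppi: Iterable[tuple[str, str, float]] | pd.DataFrame,
) -> PanCancerNetwork:
    """Merge normalized-probability protein interactions into the network.

    PPI-only pairs are added with the PPI score as weight; pairs present in
    both sources take max(co-expression frequency, PPI score).  Nodes seen
    only in the PPI are added as gene-type.  Never lowers an existing
    weight, never removes an edge.
    """
    if isinstance(ppi, pd.DataFrame):
        rows = ppi.itertuples(index=False)
    else:
        rows = iter(ppi)

    node_types = dict(net.node_types)
    edges = dict(net.edges)
    provenance = dict(net.provenance)
    for a, b, score in rows:
        score = float(score)
        if not 0 <= score <= 1:
            raise ValueError(f"PPI score {score} for ({a}, {b}) outside [0, 1]")
        if a == b:
            raise ValueError(f"PPI self-interaction on {a!r}")
        node_types.setdefault(a, GENE)
        node_types.setdefault(b, GENE)
        key = _edge_key(a, b)
        count, _ = provenance.get(key, (0, None))
        if score > 0 or key in edges:
            edges[key] = max(edges.get(key, 0.0), score) if score > 0 else edges[key]
            provenance[key] = (count, score)
        else:
            # zero-score PPI pair with no co-expression support: no edge
            continue
    return PanCancerNetwork(node_types=node_types, edges=edges, provenance=provenance)


def build_network(
    expr_matrices: Sequence[ExpressionMatrix],
    ppi: Iterable[tuple[str, str, float]] | None = None,
    gg_threshold: float = GG_THRESHOLD,
    gl_threshold: float = GL_THRESHOLD,
    *,
    signed: bool = False,
) -> PanCancerNetwork:
    """Convenience composition: per-disease co-expression -> pan-cancer
    integration -> optional PPI merge."""
    edge_sets = [
        compute_coexpression(e, gg_threshold, gl_threshold, signed=signed)
        for e in expr_matrices
    ]
    net = integrate_pan_cancer(edge_sets)
    if ppi is not None:
        net = merge_ppi(net, ppi)
    return net


# ---------------------------------------------------------------------------
# readers / writers


def read_expression_tsv(
    path: str | Path, node_types: Mapping[str, str], disease_id: str | None = None
) -> ExpressionMatrix:
    """Read a feature x sample TSV (first column = feature id)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.isna().any().any():
        raise ValueError(f"{path}: expression matrix contains missing values")
    return ExpressionMatrix(
        values=df,
        node_types=node_types,
        disease_id=disease_id or path.stem,
    )


def read_node_types(path: str | Path) -> dict[str, str]:
    """Read a 2-column TSV (node_id, node_type)."""
    df = pd.read_csv(path, sep="\t", header=None, names=["node_id", "node_type"])
    return dict(zip(df["node_id"].astype(str), df["node_type"].astype(str)))


def read_ppi_tsv(
    path: str | Path, score_divisor: float = 1.0
) -> list[tuple[str, str, float]]:
    """Read a 3-column PPI TSV; raw scores are divided by ``score_divisor``
    (e.g., 1000 for raw STRING combined scores)."""
    df = pd.read_csv(path, sep="\t", header=None, names=["a", "b", "score"])
    return [
        (str(a), str(b), float(s) / score_divisor)
        for a, b, s in zip(df["a"], df["b"], df["score"])
    ]


def write_network(net: PanCancerNetwork, edges_path: str | Path) -> None:
    """Write edge list TSV + node-type TSV (at ``<edges_path>.nodes``)."""
    edges_path = Path(edges_path)
    rows = []
    for (a, b), w in sorted(net.edges.items()):
        count, ppi = net.provenance.get((a, b), (0, None))
        rows.append((a, b, w, count, "" if ppi is None else ppi))
    pd.DataFrame(
        rows, columns=["id_a", "id_b", "weight", "n_coexpr_diseases", "ppi_score"]
    ).to_csv(edges_path, sep="\t", index=False, float_format="%.10g")
    nodes = pd.DataFrame(sorted(net.node_types.items()), columns=["node_id", "node_type"])
    nodes.to_csv(f"{edges_path}.nodes", sep="\t", index=False, header=False)


def read_network(edges_path: str | Path) -> PanCancerNetwork:
    edges_path = Path(edges_path)
    node_types = read_node_types(f"{edges_path}.nodes")
    df = pd.read_csv(edges_path, sep="\t")
    edges: dict[tuple[str, str], float] = {}
    provenance: dict[tuple[str, str], tuple[int, float | None]] = {}
    for row in df.itertuples(index=False):
        key = _edge_key(str(row.id_a), str(row.id_b))
        edges[key] = float(row.weight)
        ppi = None if pd.isna(row.ppi_score) else float(row.ppi_score)
        provenance[key] = (int(row.n_coexpr_diseases), ppi)
    return PanCancerNetwork(node_types=node_types, edges=edges, provenance=provenance)
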