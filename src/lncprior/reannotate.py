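"""Microarray probe re-annotation to lncRNA genes.

Legacy exon arrays carry far more probes than annotated protein-coding
targets; by intersecting probe genomic coordinates with lncRNA gene models,
those probes can be repurposed to measure lncRNA expression.  The rules
implemented here are deliberately conservative:

* a probe is assigned to an lncRNA only if it falls *completely* inside one
  of that lncRNA's exons,
* a probe that overlaps any protein-coding gene's genomic span (even
  partially, even intronic) is discarded,
* a probe contained in exons of two distinct lncRNAs is discarded as
  ambiguous,
* an lncRNA is retained only if at least four probes survive for it.

Probe intensities are then log2-transformed, averaged per lncRNA and
quantile-normalized across samples.

All coordinates are 0-based half-open internally.  BED input is taken
verbatim; GFF3 (1-based closed) is converted on read.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy.stats import rankdata

logger = logging.getLogger(__name__)

MIN_PROBES_PER_LNCRNA = 4

__all__ = [
    "ProbeInterval",
    "GeneModel",
    "ProbeAssignment",
    "assign_probes",
    "summarize_lncrna_expression",
    "quantile_normalize",
    "read_probes_bed",
    "read_gene_models",
    "read_intensity_matrix",
    "MIN_PROBES_PER_LNCRNA",
]


@dataclass(frozen=True)
class ProbeInterval:
    """A probe's unique genomic placement (0-based half-open)."""

    probe_id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"probe {self.probe_id!r}: malformed interval "
                f"[{self.start}, {self.end}) (start must be < end)"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"probe {self.probe_id!r}: invalid strand {self.strand!r}")


@dataclass(frozen=True)
class GeneModel:
    """A gene with biotype, exon structure and overall genomic span.

    ``exons`` are (chrom, start, end, strand) tuples, 0-based half-open.
    ``gene_span`` defaults to the envelope of the exons.
    """

    gene_id: str
    biotype: Literal["lncRNA", "coding"]
    exons: tuple[tuple[str, int, int, str], ...]
    gene_span: tuple[str, int, int] = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.biotype not in ("lncRNA", "coding"):
            raise ValueError(f"gene {self.gene_id!r}: invalid biotype {self.biotype!r}")
        if not self.exons:
            raise ValueError(f"gene {self.gene_id!r}: exon list is empty")
        for chrom, start, end, _strand in self.exons:
            if start >= end:
                raise ValueError(
                    f"gene {self.gene_id!r}: malformed exon [{start}, {end}) on {chrom}"
                )
        if self.gene_span is None:
            chrom = self.exons[0][0]
            span = (chrom, min(e[1] for e in self.exons), max(e[2] for e in self.exons))
            object.__setattr__(self, "gene_span", span)
        else:
            chrom, lo, hi = self.gene_span
            for echrom, start, end, _ in self.exons:
                if echrom != chrom or start < lo or end > hi:
                    raise ValueError(
                        f"gene {self.gene_id!r}: exon [{start}, {end}) on {echrom} "
                        f"outside gene span {self.gene_span}"
                    )


@dataclass
class ProbeAssignment:
    """Filtered many-to-one mapping probe_id -> lncRNA gene_id."""

    probe_to_gene: dict[str, str] = field(default_factory=dict)

    @property
    def gene_to_probes(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for probe, gene in self.probe_to_gene.items():
            out.setdefault(gene, []).append(probe)
        for probes in out.values():
            probes.sort()
        return out

    @property
    def genes(self) -> set[str]:
        return set(self.probe_to_gene.values())

    def __len__(self) -> int:
        return len(self.probe_to_gene)


def _exon_trees(
    models: Iterable[GeneModel], biotype: str
) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for model in models:
        if model.biotype != biotype:
            continue
        for chrom, start, end, strand in model.exons:
            trees.setdefault(chrom, IntervalTree())[start:end] = (model.gene_id, strand)
    return trees


def _span_trees(models: Iterable[GeneModel], biotype: str) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for model in models:
        if model.biotype != biotype:
            continue
        chrom, lo, hi = model.gene_span
        strand = model.exons[0][3]
        trees.setdefault(chrom, IntervalTree())[lo:hi] = (model.gene_id, strand)
    return trees


def assign_probes(
    probes: Sequence[ProbeInterval],
    models: Sequence[GeneModel],
    *,
    stranded: bool = False,
    min_probes: int = MIN_PROBES_PER_LNCRNA,
) -> ProbeAssignment:
    """Assign probes to lncRNA genes by strict exonic containment.

    A probe is kept iff it is fully contained in >=1 exon of exactly one
    lncRNA and overlaps no protein-coding gene span.  lncRNAs with fewer
    than ``min_probes`` surviving probes are dropped entirely.

    With ``stranded=True`` both the containment test and the coding-overlap
    test require matching strands (exon arrays are unstranded at
    hybridization, so the default ignores strand).
    """
    seen: set[str] = set()
    for p in probes:
        if p.probe_id in seen:
            raise ValueError(f"duplicate probe_id {p.probe_id!r} in probe set")
        seen.add(p.probe_id)

    lnc_exons = _exon_trees(models, "lncRNA")
    coding_spans = _span_trees(models, "coding")

    candidate: dict[str, str] = {}
    for probe in probes:
        tree = lnc_exons.get(probe.chrom)
        if tree is None:
            continue
        hosts = {
            gene_id
            for iv in tree.overlap(probe.start, probe.end)
            for gene_id, strand in (iv.data,)
            if iv.begin <= probe.start
            and probe.end <= iv.end
            and (not stranded or strand == probe.strand)
        }
        if len(hosts) != 1:
            # 0: not exonic; >1: ambiguous between lncRNAs -> discard
            continue
        span_tree = coding_spans.get(probe.chrom)
        if span_tree is not None:
            overlaps = [
                iv
                for iv in span_tree.overlap(probe.start, probe.end)
                if not stranded or iv.data[1] == probe.strand
            ]
            if overlaps:
                continue
        candidate[probe.probe_id] = next(iter(hosts))

    counts: dict[str, int] = {}
    for gene in candidate.values():
        counts[gene] = counts.get(gene, 0) + 1
    kept = {
        probe: gene
        for probe, gene in candidate.items()
        if counts[gene] >= min_probes
    }
    return ProbeAssignment(probe_to_gene=dict(sorted(kept.items())))


def quantile_normalize(
    m: pd.DataFrame | np.ndarray,
    *,
    ties: Literal["ordinal", "average"] = "ordinal",
) -> pd.DataFrame | np.ndarray:
    """Quantile-normalize a feature x sample matrix across columns.

    Every column is mapped onto the common reference distribution (the
    vector of row means of the column-sorted matrix).  With
    ``ties="ordinal"`` (default) tied values are assigned in stable input
    order, so every column's multiset of values ends up identical.  With
    ``ties="average"`` tied values within a column share the mean of the
    reference values at their rank positions (limma-style).
    """
    values = m.to_numpy(dtype=float) if isinstance(m, pd.DataFrame) else np.asarray(m, dtype=float)
    if values.size == 0:
        raise ValueError("quantile_normalize: empty matrix")
    if values.ndim != 2:
        raise ValueError("quantile_normalize: expected a 2-D matrix")
    if np.isnan(values).any():
        raise ValueError("quantile_normalize: missing values are not supported")

    order = np.argsort(values, axis=0, kind="stable")
    ref = np.take_along_axis(values, order, axis=0).mean(axis=1)

    if ties == "ordinal":
        out = np.empty_like(values)
        np.put_along_axis(out, order, ref[:, None], axis=0)
    elif ties == "average":
        out = np.empty_like(values)
        for j in range(values.shape[1]):
            ranks = rankdata(values[:, j], method="average")  # 1-based, .5 on ties
            lo = np.floor(ranks).astype(int) - 1
            hi = np.ceil(ranks).astype(int) - 1
            out[:, j] = 0.5 * (ref[lo] + ref[hi])
    else:
        raise ValueError(f"unknown ties mode {ties!r}")

    if isinstance(m, pd.DataFrame):
        return pd.DataFrame(out, index=m.index, columns=m.columns)
    return out


def summarize_lncrna_expression(
    raw: pd.DataFrame,
    assignment: ProbeAssignment,
    *,
    ties: Literal["ordinal", "average"] = "ordinal",
) -> pd.DataFrame:
    """Collapse a probe x sample intensity matrix to an lncRNA x sample matrix.

    Pipeline order is fixed: per-probe log2 -> per-lncRNA arithmetic mean
    over its assigned probes -> quantile normalization across samples.
    Intensities must be strictly positive.
    """
    missing = sorted(set(assignment.probe_to_gene) - set(raw.index))
    if missing:
        raise ValueError(
            f"assigned probes missing from intensity matrix: {missing[:5]}"
            + ("..." if len(missing) > 5 else "")
        )
    if len(assignment) == 0:
        raise ValueError("empty probe assignment: no lncRNA expression to summarize")

    sub = raw.loc[sorted(assignment.probe_to_gene)]
    vals = sub.to_numpy(dtype=float)
    if np.isnan(vals).any():
        raise ValueError("intensity matrix contains missing values")
    if (vals <= 0).any():
        bad = sub.index[np.where(vals <= 0)[0][0]]
        raise ValueError(f"nonpositive intensity for probe {bad!r}: log2 undefined")

    logged = np.log2(vals)
    genes = pd.Index([assignment.probe_to_gene[p] for p in sub.index], name="gene_id")
    per_gene = (
        pd.DataFrame(logged, index=genes, columns=sub.columns)
        .groupby(level=0)
        .mean()
        .sort_index()
    )
    return quantile_normalize(per_gene, ties=ties)


# ---------------------------------------------------------------------------
# readers / writers


def read_probes_bed(path: str | Path) -> list[ProbeInterval]:
    """Read probe intervals from BED6 (name column = probe id)."""
    probes = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 4:
            raise ValueError(f"{path}:{lineno}: BED line has fewer than 4 columns")
        chrom, start, end, name = fields[:4]
        strand = fields[5] if len(fields) >= 6 else "+"
        probes.append(ProbeInterval(name, chrom, int(start), int(end), strand))
    return probes


def _parse_gff3_attributes(attr: str) -> dict[str, str]:
    out = {}
    for piece in attr.strip().split(";"):
        if not piece:
            continue
        key, _, value = piece.partition("=")
        out[key.strip()] = value.strip()
    return out


def _read_gene_models_gff3(path: Path) -> list[GeneModel]:
    spans: dict[str, tuple[str, int, int]] = {}
    biotypes: dict[str, str] = {}
    exons: dict[str, list[tuple[str, int, int, str]]] = {}
    order: list[str] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 9:
            raise ValueError(f"{path}:{lineno}: GFF3 line has fewer than 9 columns")
        chrom, _src, ftype, start, end, _score, strand, _frame, attr = fields[:9]
        attrs = _parse_gff3_attributes(attr)
        # GFF3 is 1-based closed; convert to 0-based half-open
        start0, end0 = int(start) - 1, int(end)
        if ftype == "gene":
            gene_id = attrs.get("ID") or attrs.get("gene_id")
            if gene_id is None:
                raise ValueError(f"{path}:{lineno}: gene feature lacks ID/gene_id")
            biotype = attrs.get("gene_biotype") or attrs.get("biotype")
            if biotype is None:
                raise ValueError(f"{path}:{lineno}: gene {gene_id!r} lacks gene_biotype")
            biotypes[gene_id] = "coding" if biotype == "protein_coding" else biotype
            spans[gene_id] = (chrom, start0, end0)
            order.append(gene_id)
        elif ftype == "exon":
            parent = attrs.get("Parent") or attrs.get("gene_id")
            if parent is None:
                raise ValueError(f"{path}:{lineno}: exon feature lacks Parent/gene_id")
            exons.setdefault(parent, []).append((chrom, start0, end0, strand))
    models = []
    for gene_id in order:
        if gene_id not in exons:
            raise ValueError(f"{path}: gene {gene_id!r} has no exon features")
        models.append(
            GeneModel(
                gene_id=gene_id,
                biotype=biotypes[gene_id],  # type: ignore[arg-type]
                exons=tuple(exons[gene_id]),
                gene_span=spans[gene_id],
            )
        )
    return models


def _read_gene_models_bed12(path: Path) -> list[GeneModel]:
    """BED12 gene models; biotype read from an extra 13th column."""
    models = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 13:
            raise ValueError(
                f"{path}:{lineno}: BED12 gene models need 13 columns "
                "(12 BED fields + biotype)"
            )
        chrom, start, end, name = fields[0], int(fields[1]), int(fields[2]), fields[3]
        strand = fields[5]
        sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
        offsets = [int(x) for x in fields[11].rstrip(",").split(",")]
        biotype = fields[12]
        exon_list = tuple(
            (chrom, start + off, start + off + size, strand)
            for off, size in zip(offsets, sizes)
        )
        models.append(
            GeneModel(
                gene_id=name,
                biotype="coding" if biotype == "protein_coding" else biotype,  # type: ignore[arg-type]
                exons=exon_list,
                gene_span=(chrom, start, end),
            )
        )
    return models


def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Read gene models from minimal GFF3 (.gff/.gff3) or BED12+biotype (.bed)."""
    path = Path(path)
    if path.suffix in (".gff", ".gff3"):
        return _read_gene_models_gff3(path)
    if path.suffix == ".bed":
        return _read_gene_models_bed12(path)
    raise ValueError(f"unrecognized gene-model format: {path.name}")


def read_intensity_matrix(path: str | Path) -> pd.DataFrame:
    """Read a probe x sample TSV (first column probe_id, header = samples)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.isna().any().any():
        raise ValueError(f"{path}: intensity matrix contains missing values")
    return df
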