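"""Synthetic benchmark with planted co-expression modules.

Generates every input the pipeline consumes — multi-disease expression,
PPI edges, seed genes, a phenotype-similarity matrix, known-positive lncRNA
lists — with planted ground truth, so network construction, the walk,
phenotype integration and all ablations are testable without any download.

The generative model is a latent-factor Gaussian: members of a planted
module share a per-sample latent factor z, x = sqrt(rho)*z + sqrt(1-rho)*eps,
giving expected pairwise Pearson correlation exactly rho.  Each disease has
one primary module whose designated genes are its seeds; diseases in the
same phenotype-similarity block express all of the block's modules and
share the block's planted lncRNAs as positives.  A disease's own seeds
therefore recover only its own module's lncRNAs — the positives planted in
sibling modules are reachable only through phenotype integration, which is
what makes the integration ablations informative.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .network import GENE, LNCRNA, ExpressionMatrix
from .prioritize import PhenotypeSimilarityMatrix, SeedSet
from .reannotate import GeneModel, ProbeInterval

__all__ = [
    "SyntheticSpec",
    "Benchmark",
    "generate_benchmark",
    "write_truth",
    "read_truth",
    "ProbeFixture",
    "generate_probe_fixture",
]

_TRUTH_REQUIRED = ("spec", "diseases", "blocks", "modules", "seeds", "positives",
                   "non_disease_pool")


@dataclass
class SyntheticSpec:
    """Parameters of the planted benchmark.

    Defaults define the standard benchmark: 6 diseases in two similarity
    blocks of three, 500 genes + 200 lncRNAs, 60 samples per disease, one
    planted 30-member module per disease with within-module correlation
    0.9.
    """

    n_diseases: int = 6
    n_genes: int = 500
    n_lncrnas: int = 200
    samples_per_disease: int = 60
    n_modules: int = 6
    module_size: int = 30
    within_module_corr: float = 0.9
    noise_sd: float = 1.0
    disease_blocks: tuple[tuple[str, ...], ...] | None = None
    within_block_sim: float = 0.8
    between_block_sim: float = 0.1
    seeds_per_disease: int = 5
    planted_lnc_per_disease: int = 8
    rng_seed: int = 42

    def __post_init__(self) -> None:
        if self.disease_blocks is None:
            ids = self.disease_ids
            half = (self.n_diseases + 1) // 2
            self.disease_blocks = (tuple(ids[:half]), tuple(ids[half:]))
        self.disease_blocks = tuple(tuple(b) for b in self.disease_blocks if b)
        flat = [d for b in self.disease_blocks for d in b]
        if sorted(flat) != sorted(self.disease_ids):
            raise ValueError("disease_blocks must partition the disease ids")
        if self.module_size < self.seeds_per_disease + self.planted_lnc_per_disease:
            raise ValueError(
                "module_size must be >= seeds_per_disease + planted_lnc_per_disease"
            )
        if not 0 <= self.within_module_corr <= 1:
            raise ValueError("within_module_corr must lie in [0, 1]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if not (0 <= self.between_block_sim <= 1 and 0 <= self.within_block_sim <= 1):
            raise ValueError("block similarities must lie in [0, 1]")
        if self.n_modules < len(self.disease_blocks):
            raise ValueError("need at least one module per disease block")
        n_module_genes = self.module_size - self.planted_lnc_per_disease
        if self.n_modules * n_module_genes > self.n_genes:
            raise ValueError("modules require more genes than n_genes provides")
        if self.n_modules * self.planted_lnc_per_disease > self.n_lncrnas:
            raise ValueError("modules require more lncRNAs than n_lncrnas provides")

    @property
    def disease_ids(self) -> list[str]:
        return [f"D{i + 1}" for i in range(self.n_diseases)]


@dataclass
class Benchmark:
    """In-memory synthetic benchmark plus its ground-truth manifest."""

    spec: SyntheticSpec
    expression: dict[str, ExpressionMatrix]
    ppi: list[tuple[str, str, float]]
    seeds: dict[str, SeedSet]
    phenotype: PhenotypeSimilarityMatrix
    positives: dict[str, set[str]]
    node_types: dict[str, str]
    truth: dict

    def write(self, outdir: str | Path) -> None:
        """Emit the file formats the other modules consume, plus truth.json.

        Output is byte-identical across runs at a fixed rng_seed.
        """
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for d, expr in sorted(self.expression.items()):
            expr.values.to_csv(
                outdir / f"expr_{d}.tsv", sep="\t", float_format="%.10g",
                index_label="feature_id",
            )
        pd.DataFrame(sorted(self.node_types.items())).to_csv(
            outdir / "nodetypes.tsv", sep="\t", index=False, header=False
        )
        pd.DataFrame(sorted(self.ppi)).to_csv(
            outdir / "ppi.tsv", sep="\t", index=False, header=False,
            float_format="%.10g",
        )
        seed_rows = [
            (d, g) for d in sorted(self.seeds) for g in sorted(self.seeds[d].gene_ids)
        ]
        pd.DataFrame(seed_rows).to_csv(
            outdir / "seeds.tsv", sep="\t", index=False, header=False
        )
        self.phenotype.P.to_csv(
            outdir / "phenotype.tsv", sep="\t", float_format="%.10g",
            index_label="disease_id",
        )
        pos_rows = [
            (d, n) for d in sorted(self.positives) for n in sorted(self.positives[d])
        ]
        pd.DataFrame(pos_rows).to_csv(
            outdir / "lnc_positives.tsv", sep="\t", index=False, header=False
        )
        write_truth(self.truth, outdir / "truth.json")


def generate_benchmark(spec: SyntheticSpec | None = None) -> Benchmark:
    """Generate the planted benchmark for a spec (defaults if omitted)."""
    spec = spec or SyntheticSpec()
    rng = np.random.default_rng(spec.rng_seed)

    genes = [f"G{i + 1:04d}" for i in range(spec.n_genes)]
    lncs = [f"L{i + 1:04d}" for i in range(spec.n_lncrnas)]
    node_types = {g: GENE for g in genes} | {l: LNCRNA for l in lncs}

    n_blocks = len(spec.disease_blocks)
    n_module_genes = spec.module_size - spec.planted_lnc_per_disease

    # carve disjoint module memberships out of the feature pools
    modules: dict[str, dict[str, list[str]]] = {}
    g_cursor = l_cursor = 0
    for m in range(spec.n_modules):
        mgenes = genes[g_cursor : g_cursor + n_module_genes]
        mlncs = lncs[l_cursor : l_cursor + spec.planted_lnc_per_disease]
        g_cursor += n_module_genes
        l_cursor += spec.planted_lnc_per_disease
        modules[f"M{m + 1}"] = {
            "genes": mgenes,
            "seed_genes": mgenes[: spec.seeds_per_disease],
            "lncrnas": mlncs,
        }
    module_ids = sorted(modules)

    # modules round-robin over blocks; one primary module per disease
    block_modules = {
        b: [module_ids[m] for m in range(spec.n_modules) if m % n_blocks == b]
        for b in range(n_blocks)
    }
    disease_block = {
        d: b for b, block in enumerate(spec.disease_blocks) for d in block
    }
    primary_module = {}
    for b, block in enumerate(spec.disease_blocks):
        mods = block_modules[b]
        for k, d in enumerate(block):
            primary_module[d] = mods[k % len(mods)]

    seeds = {
        d: SeedSet(d, frozenset(modules[primary_module[d]]["seed_genes"]))
        for d in spec.disease_ids
    }
    positives = {
        d: {
            l
            for m in block_modules[disease_block[d]]
            for l in modules[m]["lncrnas"]
        }
        for d in spec.disease_ids
    }

    # expression: per disease, members of the block's modules load on shared
    # latent factors; everything else is independent noise
    all_features = genes + lncs
    feat_index = {f: i for i, f in enumerate(all_features)}
    rho = spec.within_module_corr
    expression: dict[str, ExpressionMatrix] = {}
    samples = spec.samples_per_disease
    for d in spec.disease_ids:
        x = rng.normal(0.0, 1.0, size=(len(all_features), samples))
        for m in block_modules[disease_block[d]]:
            z = rng.normal(0.0, 1.0, size=samples)
            members = modules[m]["genes"] + modules[m]["lncrnas"]
            rows = [feat_index[f] for f in members]
            x[rows] = np.sqrt(rho) * z + np.sqrt(1.0 - rho) * x[rows]
        values = 8.0 + spec.noise_sd * x
        expression[d] = ExpressionMatrix(
            values=pd.DataFrame(
                values,
                index=pd.Index(all_features, name="feature_id"),
                columns=[f"{d}_s{j + 1}" for j in range(samples)],
            ),
            node_types=node_types,
            disease_id=d,
        )

    # PPI: strong same-module gene pairs + weak random background pairs,
    # so the max-merge rule is exercised in both directions
    ppi: list[tuple[str, str, float]] = []
    seen_pairs: set[tuple[str, str]] = set()
    for m in module_ids:
        mgenes = modules[m]["genes"]
        pairs = [
            (a, b) for i, a in enumerate(mgenes) for b in mgenes[i + 1 :]
        ]
        k = min(len(mgenes), len(pairs))
        for idx in rng.choice(len(pairs), size=k, replace=False):
            a, b = pairs[idx]
            key = (a, b) if a <= b else (b, a)
            if key in seen_pairs:
                continue
            seen_pairs.add(key)
            ppi.append((*key, float(rng.uniform(0.7, 1.0))))
    n_background = spec.n_genes // 2
    while n_background > 0:
        i, j = rng.choice(spec.n_genes, size=2, replace=False)
        a, b = genes[i], genes[j]
        key = (a, b) if a <= b else (b, a)
        if key in seen_pairs:
            continue
        seen_pairs.add(key)
        ppi.append((*key, float(rng.uniform(0.1, 0.4))))
        n_background -= 1

    # block-structured phenotype similarity
    ids = spec.disease_ids
    P = np.full((len(ids), len(ids)), spec.between_block_sim)
    for block in spec.disease_blocks:
        for a in block:
            for b in block:
                P[ids.index(a), ids.index(b)] = spec.within_block_sim
    np.fill_diagonal(P, 1.0)
    phenotype = PhenotypeSimilarityMatrix(
        P=pd.DataFrame(P, index=ids, columns=ids)
    )

    all_seed_genes = {g for s in seeds.values() for g in s.gene_ids}
    truth = {
        "spec": _spec_to_json(spec),
        "diseases": ids,
        "blocks": [list(b) for b in spec.disease_blocks],
        "modules": {
            m: {k: list(v) for k, v in modules[m].items()} for m in module_ids
        },
        "seeds": {d: sorted(seeds[d].gene_ids) for d in ids},
        "positives": {d: sorted(positives[d]) for d in ids},
        "non_disease_pool": sorted(set(genes) - all_seed_genes),
    }

    return Benchmark(
        spec=spec,
        expression=expression,
        ppi=sorted(ppi),
        seeds=seeds,
        phenotype=phenotype,
        positives=positives,
        node_types=node_types,
        truth=truth,
    )


def _spec_to_json(spec: SyntheticSpec) -> dict:
    d = asdict(spec)
    d["disease_blocks"] = [list(b) for b in spec.disease_blocks]
    return d


def write_truth(truth: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(truth, indent=2, sort_keys=True) + "\n")


def read_truth(path: str | Path) -> dict:
    """Load and schema-check a truth manifest; errors name the bad field."""
    truth = json.loads(Path(path).read_text())
    for key in _TRUTH_REQUIRED:
        if key not in truth:
            raise ValueError(f"truth manifest missing field {key!r}")
    if not isinstance(truth["positives"], dict):
        raise ValueError("truth manifest field 'positives' must be a mapping")
    for d in truth["diseases"]:
        if d not in truth["seeds"]:
            raise ValueError(f"truth manifest field 'seeds' missing disease {d!r}")
        if d not in truth["positives"]:
            raise ValueError(f"truth manifest field 'positives' missing disease {d!r}")
    return truth


# ---------------------------------------------------------------------------
# probe-level fixture for the re-annotation rules


@dataclass
class ProbeFixture:
    """Small hand-enumerated probe/gene-model fixture (synthetic).

    ``expected_assignment`` and ``expected_excluded`` enumerate, probe by
    probe, the outcome each re-annotation rule forces: strict exonic
    containment, coding-span overlap exclusion, ambiguity discard and the
    >= 4 probes per lncRNA filter.
    """

    probes: list[ProbeInterval]
    models: list[GeneModel]
    intensities: pd.DataFrame
    expected_assignment: dict[str, str]
    expected_excluded: dict[str, str]  # probe_id -> reason

    @property
    def manifest(self) -> dict:
        return {
            "expected_assignment": dict(sorted(self.expected_assignment.items())),
            "expected_excluded": dict(sorted(self.expected_excluded.items())),
            "retained_lncrnas": sorted(set(self.expected_assignment.values())),
        }

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        bed_lines = [
            f"{p.chrom}\t{p.start}\t{p.end}\t{p.probe_id}\t0\t{p.strand}"
            for p in self.probes
        ]
        (outdir / "probes.bed").write_text("\n".join(bed_lines) + "\n")
        gff = ["##gff-version 3"]
        for m in self.models:
            chrom, lo, hi = m.gene_span
            strand = m.exons[0][3]
            biotype = "protein_coding" if m.biotype == "coding" else m.biotype
            gff.append(
                f"{chrom}\tsynthetic\tgene\t{lo + 1}\t{hi}\t.\t{strand}\t.\t"
                f"ID={m.gene_id};gene_biotype={biotype}"
            )
            for echrom, s, e, estrand in m.exons:
                gff.append(
                    f"{echrom}\tsynthetic\texon\t{s + 1}\t{e}\t.\t{estrand}\t.\t"
                    f"Parent={m.gene_id}"
                )
        (outdir / "models.gff3").write_text("\n".join(gff) + "\n")
        self.intensities.to_csv(
            outdir / "intensities.tsv", sep="\t", float_format="%.10g",
            index_label="probe_id",
        )
        (outdir / "manifest.json").write_text(
            json.dumps(self.manifest, indent=2, sort_keys=True) + "\n"
        )


def generate_probe_fixture(n_samples: int = 3) -> ProbeFixture:
    """Build the deterministic probe fixture exercising every filter rule."""
    P = ProbeInterval
    probes = [
        # lncA: four cleanly contained probes -> retained
        P("pa1", "chr1", 110, 135), P("pa2", "chr1", 150, 175),
        P("pa3", "chr1", 310, 335), P("pa4", "chr1", 350, 375),
        # lncB: pb4 straddles the exon boundary -> only 3 survive -> dropped
        P("pb1", "chr1", 1010, 1035), P("pb2", "chr1", 1040, 1065),
        P("pb3", "chr1", 1210, 1235), P("pb4", "chr1", 1090, 1110),
        # lncC: pc5 also overlaps codingX's span -> excluded; 4 remain
        P("pc1", "chr1", 5110, 5135), P("pc2", "chr1", 5140, 5165),
        P("pc3", "chr1", 5150, 5175), P("pc4", "chr1", 5170, 5195),
        P("pc5", "chr1", 5010, 5035),
        # pd1 sits in exons of both lncD and lncE -> ambiguous, discarded;
        # lncD keeps only 3 probes -> dropped; lncE keeps 4 -> retained
        P("pd1", "chr1", 7120, 7145),
        P("pd2", "chr1", 7010, 7035), P("pd3", "chr1", 7040, 7065),
        P("pd4", "chr1", 7060, 7085),
        P("pe1", "chr1", 7210, 7235), P("pe2", "chr1", 7230, 7255),
        P("pe3", "chr1", 7250, 7275), P("pe4", "chr1", 7270, 7295),
        # pn1 falls in no annotated exon
        P("pn1", "chr1", 9000, 9025),
    ]
    models = [
        GeneModel("lncA", "lncRNA", (("chr1", 100, 200, "+"), ("chr1", 300, 400, "+"))),
        GeneModel("lncB", "lncRNA", (("chr1", 1000, 1100, "+"), ("chr1", 1200, 1300, "+"))),
        GeneModel("lncC", "lncRNA", (("chr1", 5000, 5200, "+"),)),
        GeneModel("lncD", "lncRNA", (("chr1", 7000, 7200, "+"),)),
        GeneModel("lncE", "lncRNA", (("chr1", 7100, 7300, "-"),)),
        GeneModel(
            "codingX", "coding",
            (("chr1", 2000, 2200, "+"), ("chr1", 4900, 5100, "+")),
            gene_span=("chr1", 2000, 5100),
        ),
    ]
    expected_assignment = {
        "pa1": "lncA", "pa2": "lncA", "pa3": "lncA", "pa4": "lncA",
        "pc1": "lncC", "pc2": "lncC", "pc3": "lncC", "pc4": "lncC",
        "pe1": "lncE", "pe2": "lncE", "pe3": "lncE", "pe4": "lncE",
    }
    expected_excluded = {
        "pb1": "lncRNA retained <4 probes",
        "pb2": "lncRNA retained <4 probes",
        "pb3": "lncRNA retained <4 probes",
        "pb4": "not fully contained in any exon",
        "pc5": "overlaps protein-coding gene span",
        "pd1": "ambiguous between two lncRNAs",
        "pd2": "lncRNA retained <4 probes",
        "pd3": "lncRNA retained <4 probes",
        "pd4": "lncRNA retained <4 probes",
        "pn1": "not contained in any lncRNA exon",
    }
    # deterministic strictly-positive intensities with easy log2 values
    data = {
        f"s{j + 1}": [2.0 ** (1 + (k % 4) + j) for k in range(len(probes))]
        for j in range(n_samples)
    }
    intensities = pd.DataFrame(
        data, index=pd.Index([p.probe_id for p in probes], name="probe_id")
    )
    return ProbeFixture(
        probes=probes,
        models=models,
        intensities=intensities,
        expected_assignment=expected_assignment,
        expected_excluded=expected_excluded,
    )
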