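"""Synthetic knowledge graphs and variant tables with planted graph signal.

The generator emulates the statistical structure the pipeline assumes:

* a stochastic-block multigraph over synthetic gene symbols — genes inside a
  block interact densely (``p_within``), across blocks sparsely
  (``p_between``), and every realized edge carries one of ``n_relations``
  typed relations chosen uniformly;
* driver genes clustered inside designated blocks, so that network position
  is informative about driver status;
* per-variant labels drawn from a logistic model whose logit combines a
  gene-level graph term (``graph_signal`` if the gene is a driver gene), a
  variant-level term carried by a subset of the 91 feature columns
  (``variant_signal``), and Gaussian noise;
* a 91-column feature table matching the real schema (88 sequence/structure
  columns + 3 hotspot p-value columns), with signal written into
  ``n_signal_columns`` of them, the rest independent noise, and a
  configurable fraction of cells masked missing.

Everything is bit-reproducible under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .dataset import PVALUE_COLUMNS, VARIANT_FEATURE_COLUMNS, VariantRecord
from .graph_io import KnowledgeGraph, RelationLabel

__all__ = [
    "SynthConfig",
    "imbalanced_corpus",
    "simulate_graph",
    "simulate_variants",
    "make_benchmark_split",
]


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for the synthetic benchmark.

    Defaults give a 60-gene, 2-block interaction graph (within-block edge
    probability 0.3, between 0.02, two relation types) with a quarter of the
    genes — all in block 0 — designated driver genes, ~8 variants per gene
    at a 25% driver base rate, and both graph-level and variant-level signal
    present (graph_signal 1.5, variant_signal 1.0).
    """

    n_genes: int = 60
    n_blocks: int = 2
    p_within: float = 0.3
    p_between: float = 0.02
    n_relations: int = 2
    n_driver_genes: int = 15
    drivers_per_gene: float = 2.0  # mean driver count per driver gene
    passengers_per_gene: float = 6.0  # mean passenger count per gene
    graph_signal: float = 1.5  # beta_g, logit shift for driver-block genes
    variant_signal: float = 1.0  # beta_v, weight of the variant-level signal
    noise_sd: float = 0.5
    n_signal_columns: int = 5  # feature columns carrying the variant signal
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.p_within, self.p_between, self.missing_rate):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.graph_signal < 0 or self.variant_signal < 0:
            raise ValueError("signal strengths must be >= 0")
        if self.n_driver_genes > self.n_genes:
            raise ValueError("n_driver_genes cannot exceed n_genes")
        if not 1 <= self.n_signal_columns <= len(VARIANT_FEATURE_COLUMNS):
            raise ValueError("n_signal_columns out of range")

    @property
    def gene_names(self) -> tuple[str, ...]:
        return tuple(f"G{i:04d}" for i in range(self.n_genes))

    def gene_block(self, i: int) -> int:
        return i % self.n_blocks

    @property
    def driver_genes(self) -> tuple[str, ...]:
        """Driver genes fill the driver blocks round-robin, starting at block 0."""
        blocks_needed = max(1, int(np.ceil(self.n_driver_genes * self.n_blocks
                                           / max(self.n_genes, 1))))
        chosen = []
        for i, name in enumerate(self.gene_names):
            if self.gene_block(i) < blocks_needed and len(chosen) < self.n_driver_genes:
                chosen.append(name)
        return tuple(chosen)


def imbalanced_corpus(seed: int = 0) -> SynthConfig:
    """Conditions shaped like a real driver/passenger corpus.

    Real training corpora confine driver mutations to a small fraction of
    genes and carry a deep pool of passengers in driver-free genes — the
    regime the three-step sampler is designed for.  This configuration uses
    120 genes of which 10% are driver genes, ~12 variants per gene at an
    ~8% driver base rate, and a strong gene-level concentration
    (graph_signal 4) so that drivers land almost exclusively in driver
    genes; the per-gene driver-count median then caps genes the way a real
    corpus does, while driver-free genes retain enough passengers for the
    4:1 ratio.
    """
    return SynthConfig(
        n_genes=120,
        n_blocks=2,
        n_driver_genes=12,
        drivers_per_gene=1.0,
        passengers_per_gene=11.0,
        graph_signal=4.0,
        variant_signal=1.0,
        noise_sd=0.5,
        seed=seed,
    )


def simulate_graph(cfg: SynthConfig) -> KnowledgeGraph:
    """Stochastic-block multigraph with uniformly assigned typed edges."""
    rng = np.random.default_rng(cfg.seed)
    genes = cfg.gene_names
    relations = [
        RelationLabel(f"relation_{k}", "synthetic") for k in range(cfg.n_relations)
    ]
    edges = []
    for i, j in combinations(range(cfg.n_genes), 2):
        p = cfg.p_within if cfg.gene_block(i) == cfg.gene_block(j) else cfg.p_between
        if rng.random() < p:
            r = relations[int(rng.integers(0, cfg.n_relations))]
            edges.append((genes[i], r, genes[j]))
    return KnowledgeGraph.build(edges, extra_nodes=genes)


def simulate_variants(
    g: KnowledgeGraph, cfg: SynthConfig
) -> tuple[list[VariantRecord], pd.DataFrame]:
    """Variant records plus the matching 91-column feature table.

    Per gene the variant count is Poisson with mean ``drivers_per_gene +
    passengers_per_gene``; each variant's driver label is Bernoulli with

        logit p = logit(base_rate) + beta_g·(±1 for driver/non-driver gene)
                  + beta_v·s_i + noise,   s_i ~ N(0, 1)

    The graph term is coded symmetrically (+beta_g for driver genes, -beta_g
    otherwise) so that as beta_g grows the labels converge to pure block
    membership, while beta_g = 0 leaves prevalence at the base rate.

    where the latent variant signal ``s_i`` is written (with independent
    N(0, 0.5) perturbations) into the first ``n_signal_columns`` feature
    columns; the remaining columns are N(0, 1) noise, except the hotspot
    p-value columns which are Uniform(0, 1) when not carrying signal.
    Signal-carrying p-value columns get ``expit(-s_i)`` so small p-values
    track driver-ness, respecting the [0, 1] range.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    mean_variants = cfg.drivers_per_gene + cfg.passengers_per_gene
    base_rate = cfg.drivers_per_gene / mean_variants
    intercept = float(logit(base_rate))
    driver_genes = set(cfg.driver_genes)
    signal_cols = set(VARIANT_FEATURE_COLUMNS[: cfg.n_signal_columns])

    records: list[VariantRecord] = []
    rows: list[np.ndarray] = []
    genes_in_graph = [n for n in g.nodes]
    for gene in genes_in_graph:
        n_var = int(rng.poisson(mean_variants))
        for v in range(n_var):
            s = float(rng.standard_normal())
            eta = (
                intercept
                + cfg.graph_signal * (1.0 if gene in driver_genes else -1.0)
                + cfg.variant_signal * s
                + cfg.noise_sd * float(rng.standard_normal())
            )
            label = "driver" if rng.random() < expit(eta) else "passenger"
            records.append(VariantRecord(gene, f"p.X{v + 1}Y", label))
            row = np.empty(len(VARIANT_FEATURE_COLUMNS))
            for ci, col in enumerate(VARIANT_FEATURE_COLUMNS):
                if col in signal_cols:
                    if col in PVALUE_COLUMNS:
                        row[ci] = float(expit(-(s + 0.5 * rng.standard_normal())))
                    else:
                        row[ci] = s + 0.5 * rng.standard_normal()
                elif col in PVALUE_COLUMNS:
                    row[ci] = float(rng.random())
                else:
                    row[ci] = float(rng.standard_normal())
            rows.append(row)

    features = pd.DataFrame(
        np.asarray(rows),
        index=pd.MultiIndex.from_tuples(
            [r.key for r in records], names=["gene", "protein_change"]
        ),
        columns=list(VARIANT_FEATURE_COLUMNS),
    )
    if cfg.missing_rate > 0:
        mask = rng.random(features.shape) < cfg.missing_rate
        features = features.mask(mask)
    return records, features


def make_benchmark_split(
    records: list[VariantRecord],
    fraction: float,
    seed: int = 0,
    inject_overlap: int = 0,
) -> tuple[list[VariantRecord], list[VariantRecord]]:
    """Split records into (train, benchmark) disjointly by variant key.

    ``fraction`` is the share assigned to training.  ``inject_overlap`` copies
    that many training records into the benchmark to exercise overlap
    removal downstream.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(records))
    n_train = int(round(fraction * len(records)))
    train = [records[i] for i in sorted(order[:n_train])]
    bench = [records[i] for i in sorted(order[n_train:])]
    if inject_overlap:
        if inject_overlap > len(train):
            raise ValueError("cannot inject more overlap than training records")
        bench = list(train[:inject_overlap]) + bench
    return train, bench
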