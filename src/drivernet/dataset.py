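"""Variant tables, imbalance-correcting sampling, and feature assembly.

Somatic missense variants are keyed by ``(gene symbol, protein change)`` and
labeled driver / passenger / unknown.  Each variant carries 91 numeric
features: 88 precomputed sequence/structure/conservation features plus the
hotspot-region p-values from windowed 1D hotspot detection at window sizes
0, 5 and 10 (columns ``pvalue_w0``, ``pvalue_w5``, ``pvalue_w10``).

Driver/passenger corpora are doubly imbalanced — drivers concentrate in few
genes, and passengers vastly outnumber drivers.  ``sample_training_set``
applies the three-step correction:

1. per gene, keep at most ``cap`` drivers and at most ``cap`` passengers,
   chosen uniformly at random, where ``cap`` defaults to the median driver
   count over driver-bearing genes;
2. every surviving passenger in a gene that still has a driver is kept
   unconditionally (prevents the classifier from keying on gene identity);
3. passengers from driver-free genes are sampled so that the final total is
   exactly ``passenger_ratio`` x the driver total (step-2 passengers count
   toward the total).

Totals are invariant to the seed; only the membership varies.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .gnn import EmbeddingTable

__all__ = [
    "VariantRecord",
    "SamplingConfig",
    "TrainingSet",
    "FeatureMatrix",
    "VARIANT_FEATURE_COLUMNS",
    "PVALUE_COLUMNS",
    "load_variants",
    "compute_gene_cap",
    "sample_training_set",
    "assemble_features",
    "drop_overlap",
]

PVALUE_COLUMNS = ("pvalue_w0", "pvalue_w5", "pvalue_w10")
#: Canonical 91-column variant feature schema: 88 sequence/structure features
#: plus the three hotspot p-value columns.
VARIANT_FEATURE_COLUMNS: tuple[str, ...] = tuple(
    f"snvbox_{i:02d}" for i in range(1, 89)
) + PVALUE_COLUMNS

_LABELS = {"driver", "passenger", "unknown"}


@dataclass(frozen=True, order=True)
class VariantRecord:
    gene: str
    protein_change: str
    label: str

    def __post_init__(self) -> None:
        if not self.gene:
            raise ValueError("gene symbol must be non-empty")
        if self.label not in _LABELS:
            raise ValueError(f"unknown label {self.label!r}")

    @property
    def key(self) -> tuple[str, str]:
        return (self.gene, self.protein_change)


@dataclass(frozen=True)
class SamplingConfig:
    """Cap ('median' for automatic), passenger:driver ratio, and seed."""

    cap: int | str = "median"
    passenger_ratio: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.cap, str):
            if self.cap != "median":
                raise ValueError("cap must be a positive integer or 'median'")
        elif self.cap < 1:
            raise ValueError("cap must be a positive integer or 'median'")
        if self.passenger_ratio < 1:
            raise ValueError("passenger_ratio must be >= 1")


@dataclass
class TrainingSet:
    """Sampled labeled variants with per-record provenance tags."""

    records: list[VariantRecord]
    provenance: list[str]  # capped | always_included | ratio_sampled

    @property
    def n_drivers(self) -> int:
        return sum(1 for r in self.records if r.label == "driver")

    @property
    def n_passengers(self) -> int:
        return sum(1 for r in self.records if r.label == "passenger")


@dataclass
class FeatureMatrix:
    """Assembled design matrix: 91 variant columns then C graph columns."""

    X: pd.DataFrame  # indexed by (gene, protein_change)
    y: np.ndarray  # 1 = driver, 0 = passenger
    variant_columns: tuple[str, ...]
    graph_columns: tuple[str, ...]
    imputation_means: pd.Series
    missing_graph_genes: tuple[str, ...]

    @property
    def width(self) -> int:
        return self.X.shape[1]

    @property
    def feature_names(self) -> tuple[str, ...]:
        return tuple(self.X.columns)


def load_variants(source: str | IO[str]) -> list[VariantRecord]:
    """Read a variant TSV with columns gene, protein_change, label.

    Labels are normalized case-insensitively; duplicate (gene, protein_change)
    keys and unknown label values are rejected.
    """
    df = pd.read_csv(source, sep="\t", dtype=str)
    required = {"gene", "protein_change", "label"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"variant table missing column(s) {sorted(missing)}")
    labels = df["label"].str.lower()
    bad = sorted(set(labels) - _LABELS)
    if bad:
        raise ValueError(f"unknown label value(s): {bad}")
    keys = list(zip(df["gene"], df["protein_change"]))
    dupes = pd.Series(keys)[pd.Series(keys).duplicated()].unique().tolist()
    if dupes:
        raise ValueError(f"duplicate variant key(s): {dupes}")
    return [
        VariantRecord(g, p, lab)
        for g, p, lab in zip(df["gene"], df["protein_change"], labels)
    ]


def compute_gene_cap(records: Sequence[VariantRecord]) -> int:
    """Median per-gene driver count over genes with at least one driver.

    For an even number of genes the lower middle is taken, keeping the cap an
    integer count of mutations.
    """
    counts: dict[str, int] = {}
    for r in records:
        if r.label == "driver":
            counts[r.gene] = counts.get(r.gene, 0) + 1
    if not counts:
        raise ValueError("no driver records: gene cap is undefined")
    ordered = sorted(counts.values())
    return int(ordered[(len(ordered) - 1) // 2])


def sample_training_set(
    records: Sequence[VariantRecord], cfg: SamplingConfig
) -> TrainingSet:
    """Three-step imbalance-correcting sampler (see module docstring)."""
    rng = np.random.default_rng(cfg.seed)
    cap = compute_gene_cap(records) if cfg.cap == "median" else int(cfg.cap)

    by_gene: dict[str, dict[str, list[VariantRecord]]] = {}
    for r in records:
        if r.label == "unknown":
            continue
        by_gene.setdefault(r.gene, {"driver": [], "passenger": []})[r.label].append(r)

    def pick(pool: list[VariantRecord], k: int) -> list[VariantRecord]:
        pool = sorted(pool)  # canonical order; selection then depends only on seed
        if len(pool) <= k:
            return pool
        chosen = rng.choice(len(pool), size=k, replace=False)
        return [pool[i] for i in sorted(chosen)]

    drivers: list[VariantRecord] = []
    always_passengers: list[VariantRecord] = []
    free_pool: list[VariantRecord] = []
    for gene in sorted(by_gene):
        kept_d = pick(by_gene[gene]["driver"], cap)
        kept_p = pick(by_gene[gene]["passenger"], cap)
        drivers.extend(kept_d)
        if kept_d:
            always_passengers.extend(kept_p)  # step 2
        else:
            free_pool.extend(kept_p)

    n_drivers = len(drivers)
    if n_drivers == 0:
        raise ValueError("sampling produced no drivers")
    target_passengers = cfg.passenger_ratio * n_drivers
    need = target_passengers - len(always_passengers)
    if need < 0:
        raise ValueError(
            "always-included passengers "
            f"({len(always_passengers)}) already exceed the target "
            f"{cfg.passenger_ratio} x {n_drivers} = {target_passengers}; "
            "the exact ratio cannot be met"
        )
    if need > len(free_pool):
        raise ValueError(
            f"insufficient passengers in driver-free genes: need {need}, "
            f"have {len(free_pool)} (drivers={n_drivers}, "
            f"always_included={len(always_passengers)})"
        )
    sampled = pick(free_pool, need)

    records_out = drivers + always_passengers + sampled
    provenance = (
        ["capped"] * len(drivers)
        + ["always_included"] * len(always_passengers)
        + ["ratio_sampled"] * len(sampled)
    )
    return TrainingSet(records_out, provenance)


def assemble_features(
    ts: TrainingSet | Sequence[VariantRecord],
    vft: pd.DataFrame,
    emb: EmbeddingTable,
    imputation_means: pd.Series | None = None,
    strict_schema: bool = True,
) -> FeatureMatrix:
    """Join variant features and graph features into one design matrix.

    ``vft`` must be indexed by (gene, protein_change) or carry those columns.
    Missing cells are imputed with the column mean fitted on THIS call's rows
    unless ``imputation_means`` is supplied (pass the training matrix's means
    when assembling validation or benchmark data, to avoid leakage).  Genes
    absent from the embedding table receive a zero graph vector and are
    recorded in ``missing_graph_genes``.
    """
    records = ts.records if isinstance(ts, TrainingSet) else list(ts)
    if not records:
        raise ValueError("no records to assemble")
    vft = vft.copy()
    if not isinstance(vft.index, pd.MultiIndex):
        if {"gene", "protein_change"} <= set(vft.columns):
            vft = vft.set_index(["gene", "protein_change"])
        else:
            raise ValueError(
                "feature table must be indexed by (gene, protein_change)"
            )
    if strict_schema:
        expected = set(VARIANT_FEATURE_COLUMNS)
        got = set(vft.columns)
        if got != expected:
            extra = sorted(got - expected)[:5]
            missing = sorted(expected - got)[:5]
            raise ValueError(
                f"feature table does not match the 91-column schema "
                f"(missing {missing}, unexpected {extra})"
            )
        vft = vft[list(VARIANT_FEATURE_COLUMNS)]
    for col in PVALUE_COLUMNS:
        if col in vft.columns:
            vals = vft[col].dropna()
            if ((vals < 0) | (vals > 1)).any():
                raise ValueError(f"{col} contains values outside [0, 1]")

    keys = [r.key for r in records]
    missing_rows = [k for k in keys if k not in vft.index]
    if missing_rows:
        raise KeyError(f"no feature row for variant key(s): {missing_rows[:10]}")
    X_var = vft.loc[keys].astype(float)
    X_var.index = pd.MultiIndex.from_tuples(keys, names=["gene", "protein_change"])

    if imputation_means is None:
        imputation_means = X_var.mean(axis=0, skipna=True)
    imputation_means = imputation_means.reindex(X_var.columns).fillna(0.0)
    X_var = X_var.fillna(imputation_means)

    c = emb.dim
    graph_cols = tuple(f"graph_feature_{i}" for i in range(c))
    rows = np.zeros((len(records), c))
    missing_genes = []
    for i, r in enumerate(records):
        if r.gene in emb:
            rows[i] = emb[r.gene]
        else:
            missing_genes.append(r.gene)
    X_graph = pd.DataFrame(rows, index=X_var.index, columns=list(graph_cols))

    X = pd.concat([X_var, X_graph], axis=1)
    y = np.array([1 if r.label == "driver" else 0 for r in records])
    return FeatureMatrix(
        X=X,
        y=y,
        variant_columns=tuple(X_var.columns),
        graph_columns=graph_cols,
        imputation_means=imputation_means,
        missing_graph_genes=tuple(sorted(set(missing_genes))),
    )


def drop_overlap(
    benchmark: Sequence[VariantRecord], training: Sequence[VariantRecord]
) -> list[VariantRecord]:
    """Remove benchmark records whose key appears in the training set."""
    train_keys = {r.key for r in training}
    return [r for r in benchmark if r.key not in train_keys]
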