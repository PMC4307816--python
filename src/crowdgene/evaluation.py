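"""Gene-set evaluation: overlap tests, annotation enrichment, benchmarks.

Overlap and enrichment use the one-tailed (overrepresentation)
hypergeometric test within a declared background universe — typically the
genes that appeared in at least one game. Enrichment P values are
adjusted with the Benjamini-Hochberg step-up procedure. Classifier
benchmarks restrict train/test datasets to a gene set and measure the
test accuracy of a linear support-vector machine with per-gene
standardisation fitted on the training data only.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from statsmodels.stats.multitest import multipletests

from .expression_data import ExpressionDataset, concat_samples, split_train_test


class EvaluationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Annotation catalogs (GMT)

@dataclass
class AnnotationCatalog:
    """term name -> gene set, e.g. disease or Gene Ontology associations."""

    terms: dict[str, set[str]]
    source: str = ""

    def __post_init__(self) -> None:
        for name, genes in self.terms.items():
            if not genes:
                raise EvaluationError(f"term {name!r} has an empty gene set")

    @classmethod
    def from_gmt(cls, path: str | Path, source: str = "") -> "AnnotationCatalog":
        """GMT: term <tab> description <tab> gene1 <tab> gene2 ..."""
        terms: dict[str, set[str]] = {}
        for line in Path(path).read_text().splitlines():
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise EvaluationError(f"malformed GMT line: {line[:60]!r}")
            terms[fields[0]] = {g for g in fields[2:] if g}
        return cls(terms, source or str(path))

    def to_gmt(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for name, genes in self.terms.items():
                fh.write("\t".join([name, self.source, *sorted(genes)]) + "\n")


# ---------------------------------------------------------------------------
# Overlap and enrichment

def overlap_test(
    query: set[str], reference: set[str], background: set[str]
) -> tuple[int, float]:
    """One-tailed hypergeometric overlap: k = |query ∩ reference| and
    P(X >= k) with X ~ Hypergeom(N=|background|, K=|reference|, n=|query|)."""
    for name, s in (("query", query), ("reference", reference)):
        stray = s - background
        if stray:
            raise EvaluationError(
                f"{name} genes outside the background: {sorted(stray)[:5]}"
            )
    k = len(query & reference)
    N, K, n = len(background), len(reference), len(query)
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    return k, min(p, 1.0)


@dataclass
class EnrichmentResult:
    term: str
    k: int
    K: int
    n: int
    N: int
    p_raw: float
    p_adjusted: float


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjustment, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if len(p) == 0:
        return []
    if ((p < 0) | (p > 1)).any():
        raise EvaluationError("p-values must lie in [0,1]")
    return list(multipletests(p, method="fdr_bh")[1])


def enrich(
    query: set[str], catalog: AnnotationCatalog, background: set[str]
) -> list[EnrichmentResult]:
    """Overrepresentation of catalog terms in the query, within the
    background universe. Terms are intersected with the background; terms
    overlapping the query (k >= 1) are tested and BH-adjusted together.
    Results sorted by adjusted then raw P."""
    if not query:
        raise EvaluationError("query gene set is empty")
    stray = query - background
    if stray:
        raise EvaluationError(f"query genes outside the background: {sorted(stray)[:5]}")
    N, n = len(background), len(query)
    rows = []
    for term, genes in catalog.terms.items():
        term_genes = genes & background
        if not term_genes:
            continue
        k = len(query & term_genes)
        if k < 1:
            continue
        K = len(term_genes)
        p = min(float(stats.hypergeom.sf(k - 1, N, K, n)), 1.0)
        rows.append((term, k, K, p))
    adjusted = bh_adjust([r[3] for r in rows])
    results = [
        EnrichmentResult(term, k, K, n, N, p, p_adj)
        for (term, k, K, p), p_adj in zip(rows, adjusted)
    ]
    results.sort(key=lambda r: (r.p_adjusted, r.p_raw, r.term))
    return results


def write_enrichment(results: Sequence[EnrichmentResult], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("term\tk\tK\tn\tN\tp_raw\tp_adjusted\n")
        for r in results:
            fh.write(f"{r.term}\t{r.k}\t{r.K}\t{r.n}\t{r.N}\t"
                     f"{r.p_raw:.6g}\t{r.p_adjusted:.6g}\n")


# ---------------------------------------------------------------------------
# Classifier benchmarks

@dataclass(frozen=True)
class ClassifierConfig:
    """Linear maximum-margin classifier settings (unit regularisation)."""

    kernel: str = "linear"
    C: float = 1.0


@dataclass
class BenchmarkResult:
    gene_set: str
    train_name: str
    test_name: str
    n_genes_used: int
    accuracy: float
    seed: int = 0


def benchmark_gene_set(
    genes: Iterable[str],
    train: ExpressionDataset,
    test: ExpressionDataset,
    clf_config: Optional[ClassifierConfig] = None,
    seed: int = 0,
    name: str = "query",
    train_name: str = "train",
    test_name: str = "test",
) -> BenchmarkResult:
    """Restrict both datasets to the gene set, fit the SVM on train,
    report accuracy on test. Genes absent from either dataset are dropped
    and n_genes_used reflects the usable count. Invariant to gene order
    and duplicated entries."""
    clf_config = clf_config or ClassifierConfig()
    usable = sorted(
        g for g in set(genes)
        if g in train._gene_index and g in test._gene_index
    )
    if not usable:
        raise EvaluationError("no query genes are present in both datasets")
    X_train = train.gene_rows(usable).T
    X_test = test.gene_rows(usable).T
    model = Pipeline([
        ("scale", StandardScaler()),
        ("svm", SVC(kernel=clf_config.kernel, C=clf_config.C, random_state=seed)),
    ])
    model.fit(X_train, train.labels)
    acc = float((model.predict(X_test) == test.labels).mean())
    return BenchmarkResult(name, train_name, test_name, len(usable), acc, seed)


def compare_gene_sets(
    sets: Mapping[str, Iterable[str]],
    train: ExpressionDataset,
    test: ExpressionDataset,
    clf_config: Optional[ClassifierConfig] = None,
    seeds: Sequence[int] = (0,),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Paired benchmark of several gene sets.

    For each seed the pooled samples are re-split (stratified, at the
    original test fraction) and every gene set is evaluated on that same
    split. Returns (per-run table, per-set mean/SD summary).
    """
    if len(sets) < 2:
        raise EvaluationError("need at least two gene sets to compare")
    pooled = concat_samples(train, test)
    frac = test.n_samples / pooled.n_samples
    rows = []
    for seed in seeds:
        tr, te = split_train_test(pooled, frac, seed=seed, stratified=True)
        for name, genes in sets.items():
            res = benchmark_gene_set(genes, tr, te, clf_config, seed=seed,
                                     name=name)
            rows.append({
                "gene_set": name, "seed": seed,
                "n_genes_used": res.n_genes_used, "accuracy": res.accuracy,
            })
    per_run = pd.DataFrame(rows)
    summary = (
        per_run.groupby("gene_set")["accuracy"]
        .agg(mean_accuracy="mean", sd_accuracy="std")
        .reset_index()
    )
    return per_run, summary
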