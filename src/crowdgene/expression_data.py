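"""Survival-labelled expression datasets: IO, splitting, and synthesis.

The central container is :class:`ExpressionDataset`, a genes x samples
real-valued matrix with a binary 10-year-survival label per sample
(1 = survived >= 10 years, 0 = did not). Expression values are used
as-is; no internal normalisation is applied and missing values are
rejected at load time.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split


class ExpressionDataError(ValueError):
    """Raised on malformed expression tables, labels, or synthesis specs."""


@dataclass
class ExpressionDataset:
    """Gene-by-sample expression matrix with binary survival labels.

    Parameters
    ----------
    gene_ids : ordered unique gene symbols (rows).
    sample_ids : ordered unique sample identifiers (columns).
    values : float matrix of shape (len(gene_ids), len(sample_ids)),
        arbitrary (typically log-scale) expression units.
    labels : int array of 0/1 per sample; 1 = survived >= 10 years.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    labels: np.ndarray
    _gene_index: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.gene_ids = list(self.gene_ids)
        self.sample_ids = list(self.sample_ids)
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ExpressionDataError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            seen: set[str] = set()
            for g in self.gene_ids:
                if g in seen:
                    raise ExpressionDataError(f"duplicate gene symbol: {g!r}")
                seen.add(g)
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ExpressionDataError("duplicate sample identifiers")
        if self.labels.shape != (len(self.sample_ids),):
            raise ExpressionDataError("labels must be one per sample")
        if not np.isin(self.labels, (0, 1)).all():
            raise ExpressionDataError("labels must be binary (0/1)")
        if np.isnan(self.values).any():
            raise ExpressionDataError("missing values are not supported")
        self._gene_index = {g: i for i, g in enumerate(self.gene_ids)}

    # -- basic queries -------------------------------------------------

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def gene_index(self, gene: str) -> int:
        try:
            return self._gene_index[gene]
        except KeyError:
            raise KeyError(f"unknown gene: {gene!r}") from None

    def gene_rows(self, genes: Sequence[str]) -> np.ndarray:
        """Values for the given genes as an (n_genes, n_samples) view."""
        idx = [self.gene_index(g) for g in genes]
        return self.values[idx]

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionDataset":
        idx = [self.gene_index(g) for g in genes]
        return ExpressionDataset(
            [self.gene_ids[i] for i in idx], self.sample_ids,
            self.values[idx].copy(), self.labels.copy(),
        )

    def subset_samples(self, which: Sequence[int]) -> "ExpressionDataset":
        which = list(which)
        return ExpressionDataset(
            self.gene_ids, [self.sample_ids[i] for i in which],
            self.values[:, which].copy(), self.labels[which].copy(),
        )

    def fingerprint(self) -> str:
        """Stable content hash, used to key wrapper-score caches."""
        h = hashlib.sha1()
        h.update("\x00".join(self.gene_ids).encode())
        h.update("\x00".join(self.sample_ids).encode())
        h.update(self.values.tobytes())
        h.update(self.labels.tobytes())
        return h.hexdigest()

    # -- IO ------------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids,
                            columns=self.sample_ids)

    def write(self, expression_path: str | Path, label_path: str | Path) -> None:
        frame = self.to_frame()
        frame.index.name = "gene"
        frame.to_csv(expression_path, sep="\t", float_format="%.10g")
        pd.DataFrame({"sample_id": self.sample_ids, "label": self.labels}).to_csv(
            label_path, sep="\t", header=False, index=False
        )


def concat_samples(a: ExpressionDataset, b: ExpressionDataset) -> ExpressionDataset:
    """Column-wise concatenation of two datasets sharing a gene namespace."""
    if a.gene_ids != b.gene_ids:
        raise ExpressionDataError("datasets have different gene lists")
    return ExpressionDataset(
        a.gene_ids, a.sample_ids + b.sample_ids,
        np.hstack([a.values, b.values]),
        np.concatenate([a.labels, b.labels]),
    )


def load_expression_table(path: str | Path, label_path: str | Path) -> ExpressionDataset:
    """Load a TSV expression matrix plus a two-column sample/label TSV.

    The expression file has gene symbols in the first column and a header
    row of sample IDs; the label file has no header. Samples are
    restricted to those present in both files, in the order of the
    expression header.
    """
    frame = pd.read_csv(path, sep="\t", index_col=0)
    dup = frame.index[frame.index.duplicated()]
    if len(dup):
        raise ExpressionDataError(f"duplicate gene symbol: {dup[0]!r}")
    labels_df = pd.read_csv(label_path, sep="\t", header=None,
                            names=["sample_id", "label"], dtype={0: str})
    if labels_df["sample_id"].duplicated().any():
        raise ExpressionDataError("duplicate sample in label file")
    label_map = dict(zip(labels_df["sample_id"], labels_df["label"]))
    samples = [s for s in frame.columns if s in label_map]
    if not samples:
        raise ExpressionDataError("no samples shared by expression and label files")
    labels = []
    for s in samples:
        val = label_map[s]
        if pd.isna(val) or val not in (0, 1):
            raise ExpressionDataError(f"non-binary or missing label for sample {s!r}")
        labels.append(int(val))
    values = frame[samples].to_numpy(dtype=float)
    if np.isnan(values).any():
        raise ExpressionDataError("missing values in expression matrix")
    return ExpressionDataset(list(frame.index), samples, values, np.array(labels))


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for a two-class synthetic expression cohort.

    A subset of ``n_informative`` genes carries a mean shift of
    ``effect_size`` (in units of the within-class SD ``noise_sd``)
    between the survival classes; all other genes are class-independent
    noise. Labels are Bernoulli(``class_balance``).
    """

    n_genes: int
    n_samples: int
    n_informative: int
    effect_size: float = 1.0
    class_balance: float = 0.5
    noise_sd: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes <= 0:
            raise ExpressionDataError("n_genes must be positive")
        if self.n_samples <= 0:
            raise ExpressionDataError("n_samples must be positive")
        if not 0 <= self.n_informative <= self.n_genes:
            raise ExpressionDataError("n_informative must lie in [0, n_genes]")
        if self.effect_size < 0:
            raise ExpressionDataError("effect_size must be nonnegative")
        if not 0 < self.class_balance < 1:
            raise ExpressionDataError("class_balance must lie in (0,1)")
        if self.noise_sd <= 0:
            raise ExpressionDataError("noise_sd must be positive")


def generate_synthetic_cohort(
    spec: SyntheticSpec,
) -> tuple[ExpressionDataset, set[str]]:
    """Draw a synthetic survival-labelled cohort with planted signal genes.

    Returns the dataset and the set of planted informative gene symbols.
    Fully reproducible from ``spec.seed``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    width = max(4, len(str(spec.n_genes)))
    gene_ids = [f"G{i + 1:0{width}d}" for i in range(spec.n_genes)]
    sample_ids = [f"S{j + 1:04d}" for j in range(spec.n_samples)]
    labels = (rng.random(spec.n_samples) < spec.class_balance).astype(int)
    values = rng.normal(0.0, spec.noise_sd, size=(spec.n_genes, spec.n_samples))
    informative_idx = rng.choice(spec.n_genes, size=spec.n_informative, replace=False)
    shift = spec.effect_size * spec.noise_sd
    values[np.ix_(informative_idx, np.flatnonzero(labels == 1))] += shift
    informative = {gene_ids[i] for i in informative_idx}
    return ExpressionDataset(gene_ids, sample_ids, values, labels), informative


def split_train_test(
    ds: ExpressionDataset,
    test_fraction: float,
    seed: int = 0,
    stratified: bool = True,
) -> tuple[ExpressionDataset, ExpressionDataset]:
    """Disjoint train/test partition of samples, optionally stratified."""
    if not 0 < test_fraction < 1:
        raise ExpressionDataError("test_fraction must lie in (0,1)")
    classes = np.unique(ds.labels)
    if len(classes) < 2:
        raise ExpressionDataError("both classes must be present before splitting")
    idx = np.arange(ds.n_samples)
    train_idx, test_idx = train_test_split(
        idx, test_size=test_fraction, random_state=seed,
        stratify=ds.labels if stratified else None,
    )
    train = ds.subset_samples(np.sort(train_idx))
    test = ds.subset_samples(np.sort(test_idx))
    if len(np.unique(train.labels)) < 2:
        raise ExpressionDataError("a class is absent from the training split")
    return train, test


def read_gene_list(path: str | Path) -> list[str]:
    """One gene symbol per line; blank lines ignored."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line:
            out.append(line)
    return out


def write_gene_list(genes: Iterable[str], path: str | Path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in genes))
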