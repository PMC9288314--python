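"""Per-source feature selection, equal-weight fusion and normalization.

Each omics source (copy-number variation, DNA methylation, gene-level and
isoform-level RNA expression) is reduced independently with random-forest
impurity-decrease importances; the retained blocks are then concatenated
with equal column counts ("equal-weight fusion") and min-max normalized.
Random-forest selection is used instead of projection methods such as PCA
because with tens of samples a projection can retain at most n-1 components
and discards individual informative genes.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

__all__ = [
    "Source",
    "OmicsBlock",
    "ClassProportions",
    "FeatureImportance",
    "FusedDataset",
    "gini_impurity",
    "shannon_entropy",
    "rf_feature_importance",
    "select_top_k",
    "fuse_equal_weight",
    "minmax_normalize",
]


class Source(str, enum.Enum):
    """The four omics sources, in their fixed fusion order."""

    CNV = "CNV"
    METH = "METH"
    RNA_GENE = "RNA_GENE"
    RNA_ISO = "RNA_ISO"


#: Fixed column-block order of the fused matrix.
SOURCE_ORDER: tuple[Source, ...] = (
    Source.CNV,
    Source.METH,
    Source.RNA_GENE,
    Source.RNA_ISO,
)


@dataclass
class OmicsBlock:
    """One source's samples x features matrix.

    Parameters
    ----------
    source_tag
        Which omics source the block came from.
    values
        Real-valued matrix, shape ``(n_samples, n_features)``. Must be free
        of missing values; apply an imputation policy before construction.
    sample_ids, feature_ids
        Ordered identifiers for rows and columns.
    """

    source_tag: Source
    values: np.ndarray
    sample_ids: list[str]
    feature_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        n, p = self.values.shape
        if p < 1:
            raise ValueError("a block needs at least one feature")
        if len(self.sample_ids) != n or len(self.feature_ids) != p:
            raise ValueError("identifier lengths do not match the matrix")
        if not np.isfinite(self.values).all():
            raise ValueError(
                f"{self.source_tag.value}: missing or non-finite values; "
                "impute before building the block"
            )

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def subset_samples(self, idx: np.ndarray) -> "OmicsBlock":
        return OmicsBlock(
            self.source_tag,
            self.values[idx],
            [self.sample_ids[i] for i in np.asarray(idx)],
            list(self.feature_ids),
        )

    @classmethod
    def read_tsv(cls, path: str | Path, source_tag: Source,
                 impute_median: bool = False) -> "OmicsBlock":
        """Load a delimited matrix: first row feature ids, first column sample ids."""
        df = pd.read_csv(path, sep=None, engine="python", index_col=0)
        values = df.to_numpy(dtype=float)
        if impute_median and np.isnan(values).any():
            med = np.nanmedian(values, axis=0)
            ii = np.where(np.isnan(values))
            values[ii] = np.take(med, ii[1])
        return cls(source_tag, values,
                   [str(s) for s in df.index], [str(f) for f in df.columns])

    def write_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.values, index=self.sample_ids,
                     columns=self.feature_ids).to_csv(path, sep="\t")


@dataclass
class ClassProportions:
    """Class counts and their proportions at a tree node."""

    counts: np.ndarray
    proportions: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.size == 0:
            raise ValueError("empty class counts")
        if (self.counts < 0).any():
            raise ValueError("negative class counts")
        total = self.counts.sum()
        if total == 0:
            raise ValueError("no samples at node")
        self.proportions = self.counts / total

    @classmethod
    def from_labels(cls, labels: Sequence[int]) -> "ClassProportions":
        _, counts = np.unique(np.asarray(labels), return_counts=True)
        return cls(counts)


def _as_proportions(p) -> np.ndarray:
    if isinstance(p, ClassProportions):
        return p.proportions
    arr = np.asarray(p, dtype=float)
    if arr.size == 0:
        raise ValueError("empty proportion vector")
    if (arr < 0).any() or abs(arr.sum() - 1.0) > 1e-9:
        raise ValueError("proportions must be nonnegative and sum to 1")
    return arr


def gini_impurity(p) -> float:
    """Gini impurity ``1 - sum_k p_k^2`` of a class-proportion vector.

    Lies in ``[0, 1 - 1/c]`` for ``c`` classes; 0 for a pure node.
    """
    prop = _as_proportions(p)
    return float(1.0 - np.sum(prop**2))


def shannon_entropy(p) -> float:
    """Shannon information entropy ``-sum_k p_k log2 p_k`` in bits.

    ``0 * log 0`` is taken as 0; result lies in ``[0, log2 c]``.
    """
    prop = _as_proportions(p)
    nz = prop[prop > 0]
    return float(-np.sum(nz * np.log2(nz)))


@dataclass
class FeatureImportance:
    """Normalized impurity-decrease importances for one source's features."""

    source_tag: Source
    scores: np.ndarray
    ranking: np.ndarray

    def manifest(self, feature_ids: Sequence[str]) -> pd.DataFrame:
        """Tabular (source, feature, score, rank) view, best feature first."""
        return pd.DataFrame({
            "source_tag": self.source_tag.value,
            "feature_id": [feature_ids[i] for i in self.ranking],
            "score": self.scores[self.ranking],
            "rank": np.arange(len(self.ranking)),
        })


def _rank_descending(scores: np.ndarray) -> np.ndarray:
    # stable sort on negated scores: ties fall back to ascending index
    return np.argsort(-scores, kind="stable")


def rf_feature_importance(
    block: OmicsBlock,
    labels: Sequence[int],
    n_trees: int = 500,
    criterion: str = "gini",
    seed: int = 0,
) -> FeatureImportance:
    """Score every feature by its total impurity decrease in a random forest.

    Trees are grown on bootstrap resamples with sqrt(p) feature subsampling
    per split; a feature's score is the normalized total decrease in node
    impurity (Gini or entropy) over all splits on it. Scores are nonnegative
    and sum to 1; an unsplittable (constant) feature scores exactly 0.
    """
    labels = np.asarray(labels)
    if n_trees < 1:
        raise ValueError("n_trees must be >= 1")
    if labels.shape[0] != block.n_samples:
        raise ValueError("labels do not match the sample count")
    if np.unique(labels).size < 2:
        raise ValueError("labels contain a single class; no splits definable")
    if criterion not in ("gini", "entropy"):
        raise ValueError(f"unknown criterion {criterion!r}")
    forest = RandomForestClassifier(
        n_estimators=n_trees,
        criterion=criterion,
        max_features="sqrt",
        bootstrap=True,
        random_state=int(seed),
        n_jobs=1,
    )
    forest.fit(block.values, labels)
    scores = forest.feature_importances_.astype(float)
    total = scores.sum()
    if total <= 0:
        raise ValueError("forest made no splits; importances undefined")
    scores = scores / total
    return FeatureImportance(block.source_tag, scores, _rank_descending(scores))


def select_top_k(imp: FeatureImportance, block: OmicsBlock, k: int) -> OmicsBlock:
    """Restrict a block to its k highest-scoring features.

    Columns come out ordered by descending score, ties broken by ascending
    original index; values are copied untouched.
    """
    if not 1 <= k <= block.n_features:
        raise ValueError(f"k={k} outside [1, {block.n_features}]")
    if imp.source_tag != block.source_tag:
        raise ValueError("importance/block source mismatch")
    keep = imp.ranking[:k]
    return OmicsBlock(
        block.source_tag,
        block.values[:, keep].copy(),
        list(block.sample_ids),
        [block.feature_ids[i] for i in keep],
    )


@dataclass
class FusedDataset:
    """Equal-weight fused matrix plus binary survival labels.

    Labels encode death as 1 and survival as 0. ``feature_provenance``
    records, per column, the source and original feature identifier.
    ``synthetic`` flags rows created by resampling (False for real samples).
    """

    values: np.ndarray
    labels: np.ndarray
    feature_provenance: list[tuple[Source, str]]
    sample_ids: list[str]
    synthetic: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.values.shape[0] != self.labels.shape[0]:
            raise ValueError("labels length must equal sample count")
        if len(self.feature_provenance) != self.values.shape[1]:
            raise ValueError("provenance must cover every column")
        if len(self.sample_ids) != self.values.shape[0]:
            raise ValueError("sample_ids must cover every row")
        if self.synthetic is None:
            self.synthetic = np.zeros(self.values.shape[0], dtype=bool)
        else:
            self.synthetic = np.asarray(self.synthetic, dtype=bool)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def subset(self, idx: np.ndarray) -> "FusedDataset":
        idx = np.asarray(idx)
        return FusedDataset(
            self.values[idx],
            self.labels[idx],
            list(self.feature_provenance),
            [self.sample_ids[i] for i in idx],
            self.synthetic[idx],
        )

    def write_tsv(self, path: str | Path) -> None:
        """Samples x features TSV; first column the label, provenance in headers."""
        cols = [f"{src.value}::{fid}" for src, fid in self.feature_provenance]
        df = pd.DataFrame(self.values, index=self.sample_ids, columns=cols)
        df.insert(0, "label", self.labels)
        df.to_csv(path, sep="\t")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "FusedDataset":
        df = pd.read_csv(path, sep="\t", index_col=0)
        labels = df.pop("label").to_numpy(dtype=int)
        provenance = []
        for col in df.columns:
            src, _, fid = col.partition("::")
            provenance.append((Source(src), fid))
        return cls(df.to_numpy(dtype=float), labels, provenance,
                   [str(s) for s in df.index])


def fuse_equal_weight(blocks: Sequence[OmicsBlock], labels) -> FusedDataset:
    """Concatenate four selected blocks horizontally in fixed source order.

    All blocks must share sample ids (same order) and contribute the same
    number of columns k, so each source carries equal weight in the fused
    matrix of width 4k. Cell values are passed through untouched.
    """
    if len(blocks) != len(SOURCE_ORDER):
        raise ValueError(f"expected {len(SOURCE_ORDER)} blocks, got {len(blocks)}")
    by_tag = {b.source_tag: b for b in blocks}
    if set(by_tag) != set(SOURCE_ORDER):
        raise ValueError("need exactly one block per source")
    ordered = [by_tag[tag] for tag in SOURCE_ORDER]
    ref = ordered[0]
    widths = {b.n_features for b in ordered}
    if len(widths) != 1:
        raise ValueError(f"unequal per-source widths {sorted(widths)}; "
                         "equal-weight fusion needs equal k")
    for b in ordered[1:]:
        if b.sample_ids != ref.sample_ids:
            raise ValueError("blocks disagree on sample ids/order")
    values = np.hstack([b.values for b in ordered])
    provenance = [(b.source_tag, fid) for b in ordered for fid in b.feature_ids]
    return FusedDataset(values, np.asarray(labels, dtype=int),
                        provenance, list(ref.sample_ids))


def minmax_normalize(data: FusedDataset) -> FusedDataset:
    """Rescale each column to [0, 1]; constant columns map to all zeros."""
    values, _ = minmax_fit_transform(data.values)
    return replace(data, values=values)


def minmax_fit_transform(values: np.ndarray) -> tuple[np.ndarray, tuple[np.ndarray, np.ndarray]]:
    """Column-wise (x - min)/(max - min); returns the (min, range) used."""
    lo = values.min(axis=0)
    rng = values.max(axis=0) - lo
    safe = np.where(rng > 0, rng, 1.0)
    return (values - lo) / safe, (lo, safe)


def minmax_apply(values: np.ndarray, params: tuple[np.ndarray, np.ndarray]) -> np.ndarray:
    """Apply normalization fitted elsewhere (e.g. on the training split)."""
    lo, safe = params
    return (values - lo) / safe
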