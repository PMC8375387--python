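"""Core data containers for the gene-set discrimination pipeline.

The pipeline operates on two primary objects: :class:`ExpressionDataset`, a
gene x sample matrix of log2 expression values with optional detection
p-values, gene annotations and a two-group sample assignment, and
:class:`GeneSetCollection`, an ordered, GMT-backed mapping of named gene
sets.  Downstream stages produce small result records (overlap tests,
concordance, PCA, resampling) kept here as frozen dataclasses so every stage
shares one vocabulary.
"""

from __future__ import annotations

from collections.abc import Iterable, Iterator, Mapping, Sequence
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionDataset",
    "GeneSetCollection",
    "OverlapTestResult",
    "ConcordanceResult",
    "PCAResult",
    "ResamplingResult",
    "DiscriminationReport",
]


@dataclass
class ExpressionDataset:
    """A gene x sample expression matrix with optional companions.

    Parameters
    ----------
    values
        Log2-scale expression, genes as rows and samples as columns.
    detection_p
        Optional per-gene/per-sample detection p-values in ``[0, 1]`` with
        the same shape and labels as ``values``.
    annotations
        Optional per-gene table indexed by gene identifier with columns
        ``symbol``, ``chromosome`` and ``multi_mapped`` (0/1).
    groups
        Optional sample -> group-label mapping; any comparison requires
        exactly two labels.
    condition
        The group label treated as the "condition" (knockdown, patient,
        knockout); differences are reported as condition minus control.
    provenance
        Free-form log of the transformations applied so far.
    """

    values: pd.DataFrame
    detection_p: pd.DataFrame | None = None
    annotations: pd.DataFrame | None = None
    groups: pd.Series | None = None
    condition: str | None = None
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        v = self.values
        if not isinstance(v, pd.DataFrame):
            raise TypeError("values must be a pandas DataFrame (genes x samples)")
        if v.index.duplicated().any():
            dup = v.index[v.index.duplicated()][0]
            raise ValueError(f"duplicate gene identifier: {dup!r}")
        if v.columns.duplicated().any():
            dup = v.columns[v.columns.duplicated()][0]
            raise ValueError(f"duplicate sample identifier: {dup!r}")
        if not np.isfinite(v.to_numpy(dtype=float)).all():
            raise ValueError("expression matrix contains non-finite values")
        if self.detection_p is not None:
            dp = self.detection_p
            if list(dp.index) != list(v.index) or list(dp.columns) != list(v.columns):
                raise ValueError("detection_p labels/shape must match the expression matrix")
            arr = dp.to_numpy(dtype=float)
            if arr.size and (np.isnan(arr).any() or arr.min() < 0 or arr.max() > 1):
                raise ValueError("detection p-values must lie in [0, 1]")
        if self.groups is not None:
            extra = [s for s in self.groups.index if s not in v.columns]
            if extra:
                raise ValueError(f"group labels refer to unknown samples: {extra}")
        if self.annotations is not None:
            ann = self.annotations
            required = {"symbol", "chromosome", "multi_mapped"}
            missing = required - set(ann.columns)
            if missing:
                raise ValueError(f"annotation table lacks columns: {sorted(missing)}")

    # -- accessors -------------------------------------------------------
    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def with_groups(self, groups: Mapping[str, str] | pd.Series, condition: str | None = None) -> "ExpressionDataset":
        """Return a copy with a sample->group assignment attached.

        Every dataset sample must receive a label and every label must name a
        dataset sample.
        """
        g = pd.Series(dict(groups) if not isinstance(groups, pd.Series) else groups)
        unknown = [s for s in g.index if s not in self.values.columns]
        if unknown:
            raise ValueError(f"group file names samples absent from the dataset: {unknown}")
        unlabeled = [s for s in self.values.columns if s not in g.index]
        if unlabeled:
            raise ValueError(f"dataset samples missing a group label: {unlabeled}")
        g = g.reindex(self.values.columns)
        if condition is not None and condition not in set(g):
            raise ValueError(f"condition label {condition!r} not among group labels {sorted(set(g))}")
        return replace(self, groups=g, condition=condition if condition is not None else self.condition)

    def group_samples(self) -> tuple[list[str], list[str]]:
        """Return ``(control_samples, condition_samples)`` for a two-group comparison."""
        if self.groups is None:
            raise ValueError("no sample groups attached")
        labels = sorted(set(self.groups))
        if len(labels) != 2:
            raise ValueError(f"a comparison requires exactly two group labels, found {labels}")
        cond = self.condition
        if cond is None:
            raise ValueError("dataset.condition must name the condition group for comparisons")
        if cond not in labels:
            raise ValueError(f"condition label {cond!r} not among {labels}")
        control = [l for l in labels if l != cond][0]
        ctrl_samples = [s for s in self.samples if self.groups[s] == control]
        cond_samples = [s for s in self.samples if self.groups[s] == cond]
        if len(ctrl_samples) < 2 or len(cond_samples) < 2:
            raise ValueError("each group must contain at least 2 samples for a comparison")
        return ctrl_samples, cond_samples

    def subset_genes(self, genes: Sequence[str], note: str | None = None) -> "ExpressionDataset":
        """Return a copy restricted to ``genes`` (order preserved as given)."""
        genes = list(genes)
        values = self.values.loc[genes]
        dp = self.detection_p.loc[genes] if self.detection_p is not None else None
        ann = self.annotations.loc[[g for g in genes if g in self.annotations.index]] if self.annotations is not None else None
        prov = list(self.provenance)
        if note:
            prov.append(note)
        return ExpressionDataset(values, dp, ann, self.groups, self.condition, prov)


class GeneSetCollection(Mapping):
    """An ordered collection of named gene sets (the in-memory form of a GMT file).

    Member order within a set is preserved for faithful round-tripping, but
    membership queries use frozensets.  Set names are unique; members within
    a set are unique (duplicates are removed upstream by the GMT reader).
    """

    def __init__(
        self,
        sets: Mapping[str, Iterable[str]],
        descriptions: Mapping[str, str] | None = None,
    ) -> None:
        self._members: dict[str, tuple[str, ...]] = {}
        self._frozen: dict[str, frozenset] = {}
        self._descriptions: dict[str, str] = {}
        descriptions = descriptions or {}
        for name, genes in sets.items():
            genes = tuple(genes)
            if name in self._members:
                raise ValueError(f"duplicate gene-set name: {name!r}")
            if len(genes) == 0:
                raise ValueError(f"gene set {name!r} is empty")
            if len(set(genes)) != len(genes):
                raise ValueError(f"gene set {name!r} contains duplicate genes")
            self._members[name] = genes
            self._frozen[name] = frozenset(genes)
            self._descriptions[name] = str(descriptions.get(name, ""))

    # Mapping interface: name -> frozenset of members
    def __getitem__(self, name: str) -> frozenset:
        return self._frozen[name]

    def __iter__(self) -> Iterator[str]:
        return iter(self._members)

    def __len__(self) -> int:
        return len(self._members)

    @property
    def names(self) -> list[str]:
        return list(self._members)

    def members(self, name: str) -> tuple[str, ...]:
        """Ordered members of one set."""
        return self._members[name]

    def description(self, name: str) -> str:
        return self._descriptions[name]

    def subset(self, names: Sequence[str]) -> "GeneSetCollection":
        return GeneSetCollection(
            {n: self._members[n] for n in names},
            {n: self._descriptions[n] for n in names},
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"GeneSetCollection({len(self)} sets)"


@dataclass(frozen=True)
class OverlapTestResult:
    """Cumulative hypergeometric overlap between two set-name lists."""

    universe_size: int
    list_a_size: int
    list_b_size: int
    overlap: int
    p: float
    overlap_names: tuple[str, ...]


@dataclass(frozen=True)
class ConcordanceResult:
    """Pearson concordance between two per-gene log2 fold-change vectors."""

    r: float
    p: float
    n_genes: int
    common_deregulated: tuple[str, ...] = ()


@dataclass
class PCAResult:
    """Principal components of a set-score matrix across samples.

    ``coordinates`` is samples x components (columns ``PC1`` ...), with each
    component oriented so the condition-group mean coordinate is >= the
    control-group mean (sign is otherwise arbitrary).
    """

    coordinates: pd.DataFrame
    explained_variance_ratio: np.ndarray
    components: pd.DataFrame  # components x sets (loadings)


@dataclass
class ResamplingResult:
    """Random-gene-set null for cohort-classification AUC."""

    B: int
    candidate_size: int
    observed: float
    null_aucs: np.ndarray
    p_right: float


@dataclass
class DiscriminationReport:
    """Per-cohort PC-level separation summary."""

    pca: PCAResult
    pc_tests: pd.DataFrame  # per component: t, p
    aucs: pd.Series  # per component AUC on oriented coordinates
    component: int
    resampling: ResamplingResult | None = None
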