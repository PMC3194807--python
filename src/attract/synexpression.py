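"""Synexpression decomposition of significant pathways.

Step 2 of the pipeline.  A significant pathway usually mixes several
distinct expression programs; its informative (non-flat) members are
partitioned into "synexpression groups" — subsets with near-identical
profiles across samples — by average-linkage hierarchical clustering on the
Pearson correlation distance d = 1 - r.  The number of groups is chosen
with an informativeness score: each candidate partition is scored by how
class-discriminative its group mean profiles are (the mean over groups of
the log2 F obtained by running the per-gene ANOVA on each group's mean
profile), and the smallest cluster count on the plateau of the maximum
score wins.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .enrichment import anova_f
from .io import ExpressionDataset

logger = logging.getLogger("attract")

__all__ = [
    "SynexpressionGroup",
    "InformativenessTrace",
    "correlation_distance",
    "cut_dendrogram",
    "informativeness",
    "find_synexpression",
]


@dataclass
class SynexpressionGroup:
    """One coherent expression program within a pathway."""

    pathway_id: str
    group_index: int
    member_genes: frozenset[str]
    mean_profile: pd.Series  # per-sample average log2 expression
    class_means: pd.Series   # per-class average of mean_profile

    def __len__(self) -> int:
        return len(self.member_genes)


@dataclass
class InformativenessTrace:
    """Score per candidate cluster count, and the count chosen."""

    candidate_counts: list[int]
    scores: list[float]
    chosen_c: int

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"c": self.candidate_counts, "score": self.scores})


def correlation_distance(expr_subset: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Pearson correlation distance d(i,j) = 1 - r_ij.

    Rows are genes, columns samples.  d is symmetric in [0, 2] with a zero
    diagonal.  A zero-variance gene has no defined correlation and is an
    error here — such genes should have been removed upstream as flat or
    F-undefined.
    """
    if expr_subset.shape[0] < 2:
        raise ValueError("need >= 2 genes for a distance matrix")
    X = expr_subset.to_numpy(dtype=float)
    constant = np.ptp(X, axis=1) == 0
    if constant.any():
        bad = expr_subset.index[constant].tolist()
        raise ValueError(f"zero-variance gene(s) in correlation_distance: {bad}")
    r = np.corrcoef(X)
    d = 1.0 - r
    d = (d + d.T) / 2.0           # exact symmetry despite float noise
    np.fill_diagonal(d, 0.0)
    np.clip(d, 0.0, 2.0, out=d)
    return pd.DataFrame(d, index=expr_subset.index, columns=expr_subset.index)


def _linkage_sorted(dist: pd.DataFrame) -> tuple[np.ndarray, pd.Index]:
    """Average-linkage tree over genes in lexicographic ID order.

    Sorting first makes the result deterministic and invariant to the
    caller's gene order, including when merge distances tie.
    """
    order = dist.index.sort_values()
    d = dist.loc[order, order].to_numpy(dtype=float)
    return linkage(squareform(d, checks=False), method="average"), order


def cut_dendrogram(dist: pd.DataFrame, c: int) -> pd.Series:
    """Cut the average-linkage dendrogram into ``c`` groups.

    Returns gene -> group label (1..c) in the caller's gene order.  Group
    labels are renumbered so group 1 contains the lexicographically smallest
    gene ID, making the partition deterministic.
    """
    n = dist.shape[0]
    if not 1 <= c <= n:
        raise ValueError(f"cluster count c={c} outside [1, {n}]")
    Z, order = _linkage_sorted(dist)
    labels = fcluster(Z, t=c, criterion="maxclust")
    out = pd.Series(labels, index=order).reindex(dist.index)
    return _renumber(out)


def _renumber(labels: pd.Series) -> pd.Series:
    first_seen: dict[int, int] = {}
    for g in labels.index.sort_values():
        lab = labels[g]
        if lab not in first_seen:
            first_seen[lab] = len(first_seen) + 1
    return labels.map(first_seen)


def _profile_log2f(profiles: pd.DataFrame, classes: pd.Series) -> np.ndarray:
    """log2 F of each profile (rows) treated as a single gene; NaN if constant."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ds = ExpressionDataset(profiles, classes.copy())
        table = anova_f(ds).table
    return table["log2_F"].to_numpy()


def informativeness(expr: ExpressionDataset, partition: pd.Series,
                    penalty: float = 0.0) -> float:
    """Class-informativeness of a partition of genes into groups.

    Each group's mean profile is scored by the one-way ANOVA of that profile
    across the sample classes; the score is the mean over groups of
    log2 F, minus ``penalty`` per group.  A group whose mean profile is
    constant contributes the minimum log2 F observed among the other groups
    (logged); if every profile is constant the score is 0 minus the penalty.
    """
    if partition.empty:
        raise ValueError("empty partition")
    groups = sorted(partition.unique())
    profiles = pd.DataFrame(
        {g: expr.values.loc[partition.index[partition == g]].mean(axis=0)
         for g in groups}
    ).T
    profiles.index = [f"group_{g}" for g in groups]
    log2f = _profile_log2f(profiles, expr.classes)
    if np.isnan(log2f).any():
        finite = log2f[~np.isnan(log2f)]
        floor = float(finite.min()) if finite.size else 0.0
        logger.warning("%d constant group profile(s) assigned floor log2F %.3f",
                       int(np.isnan(log2f).sum()), floor)
        log2f = np.where(np.isnan(log2f), floor, log2f)
    return float(np.mean(log2f)) - penalty * len(groups)


def find_synexpression(expr: ExpressionDataset, pathway_genes,
                       pathway_id: str = "pathway",
                       c_max: int = 10, plateau_tol: float = 0.01,
                       penalty: float = 0.0,
                       exclude: frozenset[str] | set[str] = frozenset(),
                       ) -> tuple[list[SynexpressionGroup], InformativenessTrace]:
    """Decompose a pathway into synexpression groups.

    ``exclude`` holds genes to leave out of the clustering (typically the
    pathway's flat and F-undefined genes).  Candidate counts c = 1..min(c_max,
    #eligible genes) are scored with `informativeness`; the chosen c is the
    smallest whose score is within ``plateau_tol`` (relative) of the maximum.
    With fewer than two eligible genes a single trivial group is returned
    with a warning.
    """
    eligible = [g for g in pathway_genes
                if g in expr.values.index and g not in exclude]
    eligible = [g for g in eligible
                if np.ptp(expr.values.loc[g].to_numpy()) > 0]
    eligible = sorted(set(eligible))
    if not eligible:
        raise ValueError(f"pathway {pathway_id!r} has no eligible genes")
    if len(eligible) < 2:
        warnings.warn(f"pathway {pathway_id!r} has < 2 eligible genes; "
                      "returning one trivial group")
        part = pd.Series(1, index=pd.Index(eligible))
        groups = _build_groups(expr, part, pathway_id)
        score = informativeness(expr, part, penalty)
        return groups, InformativenessTrace([1], [score], 1)

    sub = expr.values.loc[eligible]
    dist = correlation_distance(sub)
    Z, order = _linkage_sorted(dist)

    counts = list(range(1, min(c_max, len(eligible)) + 1))
    partitions: dict[int, pd.Series] = {}
    scores: list[float] = []
    for c in counts:
        labels = fcluster(Z, t=c, criterion="maxclust")
        part = _renumber(pd.Series(labels, index=order))
        partitions[c] = part
        scores.append(informativeness(expr, part, penalty))

    best = max(scores)
    threshold = best - plateau_tol * abs(best)
    chosen_c = next(c for c, s in zip(counts, scores) if s >= threshold)

    groups = _build_groups(expr, partitions[chosen_c], pathway_id)
    return groups, InformativenessTrace(counts, scores, chosen_c)


def _build_groups(expr: ExpressionDataset, partition: pd.Series,
                  pathway_id: str) -> list[SynexpressionGroup]:
    groups = []
    for idx in sorted(partition.unique()):
        members = partition.index[partition == idx]
        profile = expr.values.loc[members].mean(axis=0)
        class_means = pd.Series(
            {label: profile[expr.samples_of(label)].mean()
             for label in expr.class_labels}
        )
        groups.append(SynexpressionGroup(
            pathway_id=pathway_id, group_index=int(idx),
            member_genes=frozenset(members),
            mean_profile=profile, class_means=class_means,
        ))
    return groups
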