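"""Transcriptome-wide expansion of synexpression groups.

Step 3 of the pipeline, the discovery step: each synexpression group's mean
profile is a discriminating expression pattern, and every other gene whose
expression correlates with that pattern at least as strongly as a cutoff
(0.85 by default) is attached to the group.  Restricting candidates to
genes without any pathway annotation turns this into functional inference
for unannotated genes.  A hypergeometric (one-sided Fisher) overlap test is
provided to compare expanded sets against reference gene lists.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionDataset, PathwayCollection
from .synexpression import SynexpressionGroup

logger = logging.getLogger("attract")

__all__ = ["CorrelatedSet", "correlated_partners", "overlap_test"]


@dataclass
class CorrelatedSet:
    """Genes attached to a synexpression group by expression correlation.

    ``attached_genes`` maps gene ID -> Pearson r with the group's mean
    profile; every value is >= ``cutoff`` (or |r| >= cutoff when built with
    ``absolute=True``) and the group's own members are never included.
    ``anti_correlated`` reports genes with r <= -cutoff separately when the
    signed cutoff is in force.
    """

    pathway_id: str
    group_index: int
    cutoff: float
    attached_genes: dict[str, float]
    anti_correlated: dict[str, float]

    @property
    def source(self) -> tuple[str, int]:
        return (self.pathway_id, self.group_index)

    def __len__(self) -> int:
        return len(self.attached_genes)


def correlated_partners(expr: ExpressionDataset, group: SynexpressionGroup,
                        cutoff: float = 0.85, scope: str = "all",
                        pathways: PathwayCollection | None = None,
                        absolute: bool = False,
                        min_pairwise: bool = False) -> CorrelatedSet:
    """Find all genes correlated with a group's mean profile at >= cutoff.

    Parameters
    ----------
    scope:
        ``"all"`` considers every non-member gene in the dataset;
        ``"unannotated"`` restricts candidates to genes absent from every
        pathway in ``pathways`` (which is then required).
    absolute:
        attach on |r| >= cutoff instead of the signed r >= cutoff.  With the
        default signed rule, anti-correlated genes (r <= -cutoff) are
        reported separately, not attached.
    min_pairwise:
        additionally require each attached gene's correlation with *every*
        group member to reach the cutoff (a stricter pattern match).
    """
    if not 0.0 < cutoff <= 1.0:
        raise ValueError(f"cutoff must lie in (0, 1], got {cutoff}")
    if scope not in {"all", "unannotated"}:
        raise ValueError(f"scope must be 'all' or 'unannotated', got {scope!r}")

    candidates = expr.values.index.difference(group.member_genes, sort=False)
    if scope == "unannotated":
        if pathways is None:
            raise ValueError("scope='unannotated' requires a PathwayCollection")
        annotated = pathways.annotated_genes()
        candidates = candidates[~candidates.isin(annotated)]

    X = expr.values.loc[candidates].to_numpy(dtype=float)
    profile = group.mean_profile.reindex(expr.samples).to_numpy(dtype=float)
    if np.ptp(profile) == 0:
        raise ValueError("group mean profile is constant; correlation undefined")

    informative = np.ptp(X, axis=1) > 0
    r = np.full(X.shape[0], np.nan)
    Xc = X[informative] - X[informative].mean(axis=1, keepdims=True)
    pc = profile - profile.mean()
    r[informative] = (Xc @ pc) / (
        np.sqrt((Xc ** 2).sum(axis=1)) * np.sqrt((pc ** 2).sum())
    )

    rs = pd.Series(r, index=candidates).dropna()
    if absolute:
        hit = rs[rs.abs() >= cutoff]
        anti: pd.Series = rs.iloc[0:0]
    else:
        hit = rs[rs >= cutoff]
        anti = rs[rs <= -cutoff]

    if min_pairwise and len(hit):
        members = expr.values.loc[sorted(group.member_genes)].to_numpy(dtype=float)
        Mc = members - members.mean(axis=1, keepdims=True)
        Mn = Mc / np.sqrt((Mc ** 2).sum(axis=1, keepdims=True))
        keep = []
        for gene in hit.index:
            v = expr.values.loc[gene].to_numpy(dtype=float)
            vc = v - v.mean()
            rr = Mn @ (vc / np.sqrt((vc ** 2).sum()))
            if (rr >= cutoff).all():
                keep.append(gene)
        hit = hit.loc[keep]

    logger.info("group %s/%d: %d attached, %d anti-correlated (cutoff %.2f)",
                group.pathway_id, group.group_index, len(hit), len(anti), cutoff)
    return CorrelatedSet(
        pathway_id=group.pathway_id, group_index=group.group_index,
        cutoff=cutoff,
        attached_genes={g: float(v) for g, v in hit.items()},
        anti_correlated={g: float(v) for g, v in anti.items()},
    )


def overlap_test(set_a, set_b, universe) -> float:
    """One-sided over-representation p for the overlap of two gene sets.

    Hypergeometric upper tail P(X >= |A & B|) for the 2x2 table induced by
    membership in ``set_a`` and ``set_b`` within ``universe`` — the
    one-sided Fisher exact test used to validate expanded sets against
    reference lists.
    """
    universe = frozenset(universe)
    if not universe:
        raise ValueError("empty universe")
    a, b = frozenset(set_a), frozenset(set_b)
    if not a <= universe or not b <= universe:
        raise ValueError("set_a and set_b must be subsets of the universe")
    N, K, n = len(universe), len(a), len(b)
    k = len(a & b)
    return float(stats.hypergeom.sf(k - 1, N, K, n))
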