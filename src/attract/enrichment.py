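"""GSEA-ANOVA pathway enrichment.

Step 1 of the pipeline.  Every gene gets a one-way ANOVA F-statistic
measuring how strongly its expression separates the K sample classes:

    F_i = MSS_i / RMS_i,
    MSS_i = sum_k r_k (ybar_ik - ybar_i)^2 / (K - 1),
    RMS_i = sum_k sum_j (y_ijk - ybar_ik)^2 / (N - K),

with ybar_ik the class means and ybar_i the grand mean, so that under the
null F_i ~ F(K-1, N-K).  A pathway P with g_p detected members is then
scored with a Welch (unequal-variance) two-sample T comparing its log2 F
values to the global log2 F distribution over all G annotated genes:

    T_P = (mean_P - mean_G) / sqrt(s2_P/g_p + s2_G/G),

with the real-valued Welch-Satterthwaite degrees of freedom, and the
resulting p-values are Benjamini-Hochberg adjusted across all tested
pathways.  Large positive T_P means the pathway's genes are collectively
more class-discriminative than the annotated background.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import ExpressionDataset, PathwayCollection

logger = logging.getLogger("attract")

__all__ = [
    "GeneAnovaTable",
    "PathwayTest",
    "EnrichmentResult",
    "anova_f",
    "pathway_t",
    "bh_adjust",
    "flat_genes",
    "run_enrichment",
    "pathway_overlap",
]


@dataclass
class GeneAnovaTable:
    """Per-gene one-way ANOVA results.

    ``table`` columns:

    F
        the F-statistic; ``inf`` when the residual mean square is zero but
        the treatment mean square is not, ``NaN`` when the gene is constant
        across all samples (both mean squares zero).
    log2_F
        log2 of F, defined only for finite F > 0 (NaN otherwise).
    p_value
        upper tail of F under F(K-1, N-K).
    mss, rms
        treatment and residual mean squares (both >= 0).
    """

    table: pd.DataFrame
    group_means: pd.DataFrame
    grand_mean: pd.Series
    df_between: int
    df_within: int

    @property
    def genes(self) -> pd.Index:
        return self.table.index

    def log2f(self, genes: Iterable[str] | None = None) -> pd.Series:
        """Finite log2 F values, optionally restricted to ``genes``."""
        vals = self.table["log2_F"]
        if genes is not None:
            vals = vals.reindex([g for g in genes if g in vals.index])
        return vals.dropna()

    def defined_genes(self) -> pd.Index:
        """Genes with a finite, positive F (usable in log2 F pools)."""
        return self.table.index[self.table["log2_F"].notna()]


def anova_f(expr: ExpressionDataset) -> GeneAnovaTable:
    """Fit the per-gene fixed-effects one-way ANOVA and return F-statistics.

    Vectorised over genes.  Requires K >= 2 classes and N > K samples so the
    residual degrees of freedom N - K are positive.  Genes with zero residual
    variance but real class differences get F = inf (excluded from log2 F
    pools, with a log message); genes constant everywhere get F = NaN.
    """
    K = expr.n_classes
    N = expr.n_samples
    if N <= K:
        raise ValueError(f"need N > K for residual df (N={N}, K={K})")

    Y = expr.values.to_numpy(dtype=float)
    labels = expr.class_labels
    counts = expr.replicate_counts.to_numpy(dtype=float)

    group_means = np.empty((Y.shape[0], K))
    rss = np.zeros(Y.shape[0])
    for k, label in enumerate(labels):
        mask = (expr.classes == label).to_numpy()
        block = Y[:, mask]
        group_means[:, k] = block.mean(axis=1)
        rss += ((block - group_means[:, [k]]) ** 2).sum(axis=1)

    grand = (group_means * counts).sum(axis=1) / N
    mss_raw = (counts * (group_means - grand[:, None]) ** 2).sum(axis=1)

    mss = mss_raw / (K - 1)
    rms = rss / (N - K)

    with np.errstate(divide="ignore", invalid="ignore"):
        F = mss / rms
    # constant genes: both mean squares (numerically) zero -> undefined
    tol = np.finfo(float).eps * np.abs(Y).max(initial=1.0) ** 2 * N * 16
    constant = (mss_raw <= tol) & (rss <= tol)
    F[constant] = np.nan
    zero_resid = (rss <= tol) & ~constant
    F[zero_resid] = np.inf

    with np.errstate(divide="ignore", invalid="ignore"):
        log2F = np.where(np.isfinite(F) & (F > 0), np.log2(F), np.nan)
        p = stats.f.sf(F, K - 1, N - K)
    p[constant] = np.nan
    p[zero_resid] = 0.0

    n_const = int(constant.sum())
    n_inf = int(zero_resid.sum())
    n_zero = int(np.sum(np.isfinite(F) & (F == 0)))
    if n_const:
        logger.warning("%d constant gene(s) have undefined F and are excluded", n_const)
    if n_inf:
        logger.warning("%d gene(s) with zero residual variance have infinite F "
                       "and are excluded from log2 F pools", n_inf)
    if n_zero:
        logger.info("%d gene(s) with F = 0 excluded from log2 F pools", n_zero)

    table = pd.DataFrame(
        {"F": F, "log2_F": log2F, "p_value": p, "mss": mss, "rms": rms},
        index=expr.genes,
    )
    return GeneAnovaTable(
        table=table,
        group_means=pd.DataFrame(group_means, index=expr.genes, columns=labels),
        grand_mean=pd.Series(grand, index=expr.genes, name="grand_mean"),
        df_between=K - 1,
        df_within=N - K,
    )


class PathwayTest(NamedTuple):
    """Welch two-sample T of a pathway's log2 F values against the universe."""

    T: float
    df: float
    p_value: float
    g_p: int
    G: int
    mean_pathway: float
    mean_global: float
    var_pathway: float
    var_global: float


def pathway_t(gene_table: GeneAnovaTable, pathway_genes: Iterable[str],
              universe_genes: Iterable[str],
              one_sided: bool = False) -> PathwayTest:
    """Welch T comparing pathway log2 F values to the global distribution.

    The universe (all annotated genes) includes the pathway's own members.
    Both groups need an unbiased sample variance, hence g_p >= 2 and a
    nonzero pooled variance; otherwise the pathway cannot be tested and a
    ValueError is raised (callers skip it with a logged reason).

    ``one_sided=True`` tests for log2 F larger than the background
    (enrichment in class-discriminative genes); the default is two-sided
    with the direction carried by the sign of T.
    """
    x = gene_table.log2f(pathway_genes).to_numpy()
    g = gene_table.log2f(universe_genes).to_numpy()
    g_p, G = len(x), len(g)
    if g_p < 2:
        raise ValueError(f"pathway has {g_p} gene(s) with defined log2 F; need >= 2")
    if G < g_p:
        raise ValueError("universe smaller than the pathway")
    s2_p = float(np.var(x, ddof=1))
    s2_g = float(np.var(g, ddof=1))
    se2 = s2_p / g_p + s2_g / G
    if se2 <= 0.0:
        raise ValueError("zero pooled variance; Welch T undefined")
    T = (float(np.mean(x)) - float(np.mean(g))) / np.sqrt(se2)
    df = se2 ** 2 / ((s2_p / g_p) ** 2 / (g_p - 1) + (s2_g / G) ** 2 / (G - 1))
    if one_sided:
        p = float(stats.t.sf(T, df))
    else:
        p = float(2.0 * stats.t.sf(abs(T), df))
    return PathwayTest(T=float(T), df=float(df), p_value=min(p, 1.0),
                       g_p=g_p, G=G,
                       mean_pathway=float(np.mean(x)), mean_global=float(np.mean(g)),
                       var_pathway=s2_p, var_global=s2_g)


def bh_adjust(raw_p: Iterable[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in the input order."""
    p = np.asarray(list(raw_p), dtype=float)
    if p.size == 0:
        return p
    if np.isnan(p).any():
        raise ValueError("NaN p-value passed to bh_adjust")
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# -- flat genes ------------------------------------------------------------

def _moderated_p(gene_table: GeneAnovaTable) -> pd.Series:
    """Empirical-Bayes moderated ANOVA p-values.

    Shrinks each gene's residual mean square toward a pooled prior
    s0^2 with d0 prior degrees of freedom, fitted by moment matching under
    the scaled-F sampling model s^2 ~ s0^2 F(d, d0), then recomputes
    F = MSS / s~^2 with s~^2 = (d0 s0^2 + d s^2)/(d0 + d) and refers it to
    F(K-1, N-K+d0).
    """
    d = gene_table.df_within
    s2 = gene_table.table["rms"].to_numpy()
    ok = np.isfinite(s2) & (s2 > 0)
    m = float(np.mean(s2[ok]))
    v = float(np.var(s2[ok], ddof=1))
    c = v / m ** 2 if m > 0 else 0.0
    if c * d <= 2.0:
        d0, s0sq = np.inf, m  # no dispersion beyond sampling noise: full shrinkage
    else:
        d0 = (2.0 * d - 4.0 + 4.0 * c * d) / (c * d - 2.0)
        d0 = max(d0, 1e-3)
        s0sq = m * (d0 - 2.0) / d0 if d0 > 2.0 else m
    if np.isinf(d0):
        post = np.full_like(s2, s0sq)
        df2 = np.inf
    else:
        post = (d0 * s0sq + d * s2) / (d0 + d)
        df2 = d + d0
    with np.errstate(divide="ignore", invalid="ignore"):
        f_mod = gene_table.table["mss"].to_numpy() / post
        p = stats.f.sf(f_mod, gene_table.df_between, df2)
    return pd.Series(p, index=gene_table.genes, name="moderated_p")


def flat_genes(gene_table: GeneAnovaTable, p_threshold: float = 0.05,
               moderated: bool = False) -> frozenset[str]:
    """Genes showing no significant change across classes (p > threshold).

    By default uses the ordinary ANOVA p-value; ``moderated=True`` switches
    to an empirical-Bayes variant that shrinks per-gene residual variances
    toward a pooled prior (moment-matched), which stabilises the call for
    small replicate counts.  Constant genes (undefined F) are flat by
    definition, and a threshold >= 1 flags every gene.
    """
    if p_threshold >= 1.0:
        return frozenset(gene_table.genes)
    p = _moderated_p(gene_table) if moderated else gene_table.table["p_value"]
    flat = p.isna() | (p > p_threshold)
    return frozenset(gene_table.genes[flat.to_numpy()])


# -- pathway-level run -----------------------------------------------------

@dataclass
class EnrichmentResult:
    """Ranked pathway table plus run-level context."""

    table: pd.DataFrame
    universe: frozenset[str]
    gene_table: GeneAnovaTable
    flat: frozenset[str]
    detected: dict[str, frozenset[str]] = field(default_factory=dict)
    fdr: float = 0.05

    @property
    def significant(self) -> list[str]:
        return self.table.index[self.table["adj_p"] < self.fdr].tolist()


def run_enrichment(expr: ExpressionDataset, pathways: PathwayCollection,
                   min_size: int = 5, fdr: float = 0.05,
                   one_sided: bool = False, flat_p: float = 0.05,
                   flat_moderated: bool = False,
                   gene_table: GeneAnovaTable | None = None) -> EnrichmentResult:
    """Score every pathway with >= ``min_size`` detected members.

    A pathway's *detected* members are its genes present in the dataset with
    a finite log2 F.  The comparison universe is the union of detected genes
    over all tested pathways (it includes each pathway's own members).  The
    result table is sorted by BH-adjusted p ascending, ties broken by |T|
    descending then pathway ID.
    """
    if gene_table is None:
        gene_table = anova_f(expr)
    defined = frozenset(gene_table.defined_genes())

    detected = {
        pid: frozenset(members & defined)
        for pid, members in ((p, set(pathways[p])) for p in pathways.ids())
    }
    tested = [pid for pid, members in detected.items()
              if len(members) >= max(min_size, 2)]
    if not tested:
        raise ValueError(
            f"no pathway has >= {min_size} detected members; nothing to test"
        )
    universe: set[str] = set()
    for pid in tested:
        universe |= detected[pid]

    rows = []
    for pid in tested:
        try:
            t = pathway_t(gene_table, sorted(detected[pid]), sorted(universe),
                          one_sided=one_sided)
        except ValueError as exc:
            logger.warning("pathway %s skipped: %s", pid, exc)
            continue
        rows.append({
            "pathway_id": pid,
            "name": pathways.name_of(pid),
            "g_p": t.g_p,
            "T": t.T,
            "df": t.df,
            "raw_p": t.p_value,
            "mean_log2F_pathway": t.mean_pathway,
            "mean_log2F_global": t.mean_global,
            "var_log2F_pathway": t.var_pathway,
            "var_log2F_global": t.var_global,
            "direction": int(np.sign(t.mean_pathway - t.mean_global)),
        })
    if not rows:
        raise ValueError("every candidate pathway was skipped; nothing to test")

    table = pd.DataFrame(rows).set_index("pathway_id")
    table["adj_p"] = bh_adjust(table["raw_p"])

    flat = flat_genes(gene_table, p_threshold=flat_p, moderated=flat_moderated)
    table["flat_count"] = [len(detected[pid] & flat) for pid in table.index]

    table = table.sort_values(
        by=["adj_p", "T", "pathway_id"],
        key=lambda s: -s.abs() if s.name == "T" else s,
        ascending=[True, True, True],
    )
    order = ["name", "g_p", "T", "df", "raw_p", "adj_p",
             "mean_log2F_pathway", "mean_log2F_global",
             "var_log2F_pathway", "var_log2F_global",
             "flat_count", "direction"]
    return EnrichmentResult(table=table[order], universe=frozenset(universe),
                            gene_table=gene_table, flat=flat,
                            detected=detected, fdr=fdr)


def pathway_overlap(pathways: PathwayCollection,
                    selected: Iterable[str]) -> pd.DataFrame:
    """Pairwise membership overlap |P & Q| / min(|P|, |Q|) among ``selected``.

    Symmetric with unit diagonal; quantifies the redundancy of significant
    pathways (many genes carry multiple annotations).
    """
    selected = list(selected)
    unknown = [p for p in selected if p not in pathways]
    if unknown:
        raise KeyError(f"unknown pathway IDs: {unknown}")
    if len(selected) < 2:
        raise ValueError("need >= 2 pathways to compute overlap")
    out = pd.DataFrame(np.eye(len(selected)), index=selected, columns=selected)
    for i, p in enumerate(selected):
        for q in selected[i + 1:]:
            a, b = pathways[p], pathways[q]
            val = len(a & b) / min(len(a), len(b))
            out.loc[p, q] = out.loc[q, p] = val
    return out
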