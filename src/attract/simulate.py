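"""Synthetic multi-class expression data with planted pathway structure.

Data are drawn from the same fixed-effects model the enrichment ANOVA
assumes: y_jk = mu + mu_k + eps_jk with eps ~ N(0, sigma^2).  Planted
enriched pathways carry nonzero class effects mu_k; within a planted
pathway the genes are split into blocks with distinct class patterns
(synexpression structure); unannotated partner genes copy a block's
pattern with small independent noise; null pathways and filler genes are
flat (mu_k = 0).  A truth record lists every planted label so precision
and recall of every pipeline stage can be computed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ExpressionDataset, PathwayCollection

__all__ = ["SimulationSpec", "generate"]


@dataclass
class SimulationSpec:
    """Parameters of the planted-structure generator.

    Defaults emulate a compact four-class design with six replicates per
    class, one planted pathway among fifty null pathways, two opposed
    synexpression blocks, thirty tightly correlated unannotated partners
    per block and a background of unannotated flat genes.  ``effect_size``
    is the standard deviation of the planted class-mean pattern in units of
    the residual sigma.
    """

    n_classes: int = 4
    replicates: tuple[int, ...] = (6, 6, 6, 6)
    n_planted_pathways: int = 1
    n_null_pathways: int = 50
    pathway_size: tuple[int, int] = (10, 30)
    n_null_genes: int = 500
    effect_size: float = 1.5
    n_blocks: int = 2
    block_pattern: np.ndarray | None = None  # (n_classes x n_blocks), expression units
    partner_count: int = 30
    partner_noise: float = 0.05
    flat_fraction: float = 0.05
    noise_sd: float = 0.5
    baseline: float = 8.0
    heavy_tails: bool = False  # t(5) residuals instead of Gaussian
    overlapping_membership: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.replicates) != self.n_classes:
            raise ValueError("replicates length must equal n_classes")
        if min(self.replicates) < 2:
            raise ValueError("need >= 2 replicates per class")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        lo, hi = self.pathway_size
        if not (0 < lo <= hi):
            raise ValueError(f"invalid pathway_size range {self.pathway_size}")
        if self.n_blocks < 1:
            raise ValueError("need >= 1 block")
        if not 0 <= self.flat_fraction < 1:
            raise ValueError("flat_fraction must lie in [0, 1)")
        if self.block_pattern is not None:
            bp = np.asarray(self.block_pattern, dtype=float)
            if bp.shape != (self.n_classes, self.n_blocks):
                raise ValueError(
                    f"block_pattern must be (n_classes x n_blocks) = "
                    f"({self.n_classes} x {self.n_blocks}), got {bp.shape}"
                )
            self.block_pattern = bp


def _default_patterns(spec: SimulationSpec, rng: np.random.Generator) -> np.ndarray:
    """Class-mean patterns per block, (K x B), summing to zero across blocks.

    Patterns are centred across classes and scaled so each block's pattern
    has standard deviation effect_size * noise_sd across classes.  Blocks
    sum to zero across the block axis (for B = 2: opposite up/down
    patterns), so a pathway-wide average profile cancels — the synexpression
    phenotype the decomposition step is meant to resolve.
    """
    K, B = spec.n_classes, spec.n_blocks
    amp = spec.effect_size * spec.noise_sd
    if B == 1:
        z = rng.standard_normal(K)
        z -= z.mean()
        sd = z.std()
        if sd == 0:
            z = np.linspace(-1, 1, K)
            sd = z.std()
        return (amp * z / sd)[:, None]
    base = rng.standard_normal((K, (B + 1) // 2))
    base -= base.mean(axis=0, keepdims=True)
    cols = []
    for j in range(base.shape[1]):
        v = base[:, j]
        sd = v.std()
        if sd == 0:
            v = np.linspace(-1, 1, K)
            sd = v.std()
        v = amp * v / sd
        cols.append(v)
        cols.append(-v)
    return np.column_stack(cols[:B])


def generate(spec: SimulationSpec) -> tuple[ExpressionDataset, PathwayCollection, dict]:
    """Draw a dataset, gene sets and a truth record from ``spec``.

    Deterministic given ``spec.seed``.  The truth record contains:
    ``planted_pathways``, ``null_pathways``, ``blocks`` (pathway -> gene ->
    block index), ``partners`` (pathway -> block index -> genes),
    ``flat_genes`` (all genes with mu_k = 0, including planted members
    silenced by ``flat_fraction``) and ``patterns`` (pathway -> K x B list).
    """
    rng = np.random.default_rng(spec.seed)
    K = spec.n_classes
    class_labels = [f"C{k + 1}" for k in range(K)]
    samples, classes = [], []
    for label, r in zip(class_labels, spec.replicates):
        for j in range(r):
            samples.append(f"{label}_s{j + 1}")
            classes.append(label)
    classes = pd.Series(classes, index=samples, name="class")
    N = len(samples)
    class_idx = np.concatenate(
        [np.full(r, k) for k, r in enumerate(spec.replicates)]
    )

    lo, hi = spec.pathway_size
    sizes_planted = rng.integers(lo, hi + 1, size=spec.n_planted_pathways)
    sizes_null = rng.integers(lo, hi + 1, size=spec.n_null_pathways)

    gene_counter = 0

    def new_genes(n: int) -> list[str]:
        nonlocal gene_counter
        out = [f"G{gene_counter + i:06d}" for i in range(n)]
        gene_counter += n
        return out

    rows: list[np.ndarray] = []
    gene_ids: list[str] = []
    sets: dict[str, frozenset[str]] = {}
    names: dict[str, str] = {}
    truth: dict = {
        "planted_pathways": [], "null_pathways": [],
        "blocks": {}, "partners": {}, "flat_genes": [], "patterns": {},
    }

    def noise(n_genes: int) -> np.ndarray:
        if spec.heavy_tails:
            return spec.noise_sd * rng.standard_t(5, size=(n_genes, N))
        return spec.noise_sd * rng.normal(size=(n_genes, N))

    # planted pathways: blocks of distinct class patterns + optional flat members
    for p in range(spec.n_planted_pathways):
        pid = f"PLANTED{p + 1:02d}"
        size = int(sizes_planted[p])
        genes = new_genes(size)
        patterns = (spec.block_pattern if spec.block_pattern is not None
                    else _default_patterns(spec, rng))
        truth["patterns"][pid] = patterns.tolist()
        n_flat = int(round(spec.flat_fraction * size))
        block_of = {}
        for i, g in enumerate(genes):
            if i < size - n_flat:
                b = i % spec.n_blocks
                mu_k = patterns[:, b]
                block_of[g] = int(b)
            else:
                mu_k = np.zeros(K)
                truth["flat_genes"].append(g)
            rows.append(spec.baseline + mu_k[class_idx])
            gene_ids.append(g)
        base = noise(size)
        for i in range(size):
            rows[-size + i] = rows[-size + i] + base[i]
        sets[pid] = frozenset(genes)
        names[pid] = f"planted pathway {p + 1}"
        truth["planted_pathways"].append(pid)
        truth["blocks"][pid] = block_of

        # unannotated partner genes per block
        truth["partners"][pid] = {}
        for b in range(spec.n_blocks):
            partners = new_genes(spec.partner_count)
            for g in partners:
                prof = (spec.baseline + patterns[class_idx, b]
                        + spec.partner_noise * rng.normal(size=N))
                rows.append(prof)
                gene_ids.append(g)
            truth["partners"][pid][b] = partners

    # null pathways: flat members
    pool: list[str] = []
    for q in range(spec.n_null_pathways):
        pid = f"NULL{q + 1:03d}"
        size = int(sizes_null[q])
        if spec.overlapping_membership and pool:
            n_shared = min(size // 3, len(pool))
            shared = list(rng.choice(pool, size=n_shared, replace=False))
            fresh = new_genes(size - n_shared)
            genes = shared + fresh
        else:
            fresh = new_genes(size)
            genes = fresh
        mat = spec.baseline + noise(len(fresh))
        for g, row in zip(fresh, mat):
            rows.append(row)
            gene_ids.append(g)
            truth["flat_genes"].append(g)
        pool.extend(fresh)
        sets[pid] = frozenset(genes)
        names[pid] = f"null pathway {q + 1}"
        truth["null_pathways"].append(pid)

    # unannotated filler genes, flat
    filler = new_genes(spec.n_null_genes)
    mat = spec.baseline + noise(spec.n_null_genes)
    for g, row in zip(filler, mat):
        rows.append(row)
        gene_ids.append(g)
        truth["flat_genes"].append(g)

    values = pd.DataFrame(np.vstack(rows), index=gene_ids, columns=samples)
    expr = ExpressionDataset(values, classes)
    pathways = PathwayCollection(sets=sets, names=names)
    return expr, pathways, truth
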