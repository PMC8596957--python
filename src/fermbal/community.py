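"""Community statistics over OTU count tables.

Covers the downstream analyses of a 16S amplicon survey once counts are in
hand: rarefaction, alpha diversity (Shannon, observed species, Chao1, Faith's
phylogenetic diversity), Bray-Curtis dissimilarity, non-metric
multidimensional scaling (NMDS), PERMANOVA, family-level aggregation and
two-group Welch tests with confidence intervals.

Tables are pandas DataFrames with samples as rows and taxa as columns.
Chao1 delegates to scikit-bio; Faith's PD is computed here so multifurcating
(e.g. star) trees are accepted; PERMANOVA and NMDS are implemented here
because the result contracts require R^2, a seeded permutation stream and a
per-iteration stress trace.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from skbio import TreeNode
from skbio.diversity.alpha import chao1 as _skbio_chao1
from sklearn.isotonic import IsotonicRegression

__all__ = [
    "OrdinationResult",
    "PermanovaResult",
    "rarefy",
    "shannon",
    "observed_species",
    "chao1",
    "faith_pd",
    "alpha_diversity_table",
    "bray_curtis",
    "nmds",
    "permanova",
    "family_profile",
    "group_difference",
]


@dataclass
class OrdinationResult:
    """NMDS embedding with its Kruskal stress-1 and convergence record."""

    coordinates: pd.DataFrame  # samples x k, centered
    stress: float  # final Kruskal stress-1
    stress_trace: np.ndarray  # per-iteration stress of the winning restart
    seed: int
    n_iterations: int


@dataclass
class PermanovaResult:
    r2: float
    pseudo_f: float
    p_value: float
    n_permutations: int


# ---------------------------------------------------------------------------
# rarefaction and alpha diversity


def rarefy(table: pd.DataFrame, depth: int, seed: int) -> pd.DataFrame:
    """Subsample each sample to *depth* reads without replacement.

    Samples whose total is below the depth are dropped with a warning, as in
    the usual amplicon-pipeline convention.
    """
    if depth <= 0:
        raise ValueError("rarefaction depth must be positive")
    counts = table.to_numpy()
    if np.any(counts < 0) or not np.issubdtype(counts.dtype, np.integer):
        counts = counts.astype(np.int64)
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative integers")
    rng = np.random.default_rng(seed)
    keep, rows = [], []
    for sample, row in zip(table.index, counts):
        total = int(row.sum())
        if total < depth:
            warnings.warn(
                f"sample {sample!r} has {total} < depth {depth}; dropped",
                stacklevel=2,
            )
            continue
        rows.append(rng.multivariate_hypergeometric(row, depth))
        keep.append(sample)
    return pd.DataFrame(rows, index=keep, columns=table.columns, dtype=np.int64)


def shannon(counts: Sequence[float], base: float = 2.0) -> float:
    """Shannon diversity −Σ p_i log_base p_i over positive proportions."""
    c = np.asarray(counts, dtype=float)
    if np.any(c < 0):
        raise ValueError("counts must be non-negative")
    total = c.sum()
    if total == 0:
        raise ValueError("all-zero sample has no diversity")
    p = c[c > 0] / total
    return float(-(p * np.log(p)).sum() / np.log(base))


def observed_species(counts: Sequence[float]) -> int:
    """Number of taxa with a positive count."""
    return int((np.asarray(counts) > 0).sum())


def chao1(counts: Sequence[int], bias_corrected: bool = True) -> float:
    """Chao1 richness: S_obs + F1(F1−1)/(2(F2+1)) in the bias-corrected form."""
    return float(_skbio_chao1(np.asarray(counts, dtype=int), bias_corrected=bias_corrected))


def faith_pd(
    tree: TreeNode,
    present_taxa: Sequence[str],
    include_root: bool = True,
) -> float:
    """Faith's phylogenetic diversity of the taxa present in one sample.

    Sums branch lengths of the minimal subtree connecting *present_taxa*; by
    default the path to the tree root is included ("whole tree" convention).
    With ``include_root=False`` the root-to-crown path is excluded.
    """
    taxa = list(present_taxa)
    if not taxa:
        raise ValueError("present_taxa must be non-empty")
    leaf_names = {leaf.name for leaf in tree.tips()}
    unknown = set(taxa) - leaf_names
    if unknown:
        raise KeyError(f"taxa not in tree: {sorted(unknown)}")
    # union of root paths, each edge counted once; works for any rooted
    # topology including multifurcations (which skbio's faith_pd rejects)
    edges: dict[int, float] = {}
    for name in taxa:
        node = tree.find(name)
        while node.parent is not None:
            edges[id(node)] = node.length or 0.0
            node = node.parent
    pd_root = sum(edges.values())
    if include_root:
        return pd_root
    crown = tree.lca([tree.find(t) for t in taxa]) if len(taxa) > 1 else tree.find(taxa[0])
    drop = 0.0
    node = crown
    while node.parent is not None:
        drop += node.length or 0.0
        node = node.parent
    return pd_root - drop


def alpha_diversity_table(
    table: pd.DataFrame,
    tree: TreeNode | None = None,
    base: float = 2.0,
) -> pd.DataFrame:
    """Per-sample Shannon, observed species, Chao1 and (with a tree) Faith PD."""
    out: dict[str, dict[str, float]] = {}
    for sample, row in table.iterrows():
        counts = row.to_numpy()
        rec = {
            "shannon": shannon(counts, base=base),
            "observed_species": observed_species(counts),
            "chao1": chao1(counts.astype(int)),
        }
        if tree is not None:
            present = list(table.columns[counts > 0])
            rec["faith_pd"] = faith_pd(tree, present)
        out[sample] = rec
    return pd.DataFrame.from_dict(out, orient="index")


# ---------------------------------------------------------------------------
# beta diversity, ordination, PERMANOVA


def bray_curtis(table: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarity on counts (samples x samples)."""
    if table.shape[0] < 2:
        raise ValueError("need at least two samples")
    counts = table.to_numpy(dtype=float)
    if np.any(counts.sum(axis=1) == 0):
        raise ValueError("a sample with zero total has undefined dissimilarity")
    d = squareform(pdist(counts, metric="braycurtis"))
    return pd.DataFrame(d, index=table.index, columns=table.index)


def _check_distances(distances: pd.DataFrame | np.ndarray) -> np.ndarray:
    d = np.asarray(distances, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T) or not np.allclose(np.diag(d), 0.0):
        raise ValueError("distance matrix must be symmetric with zero diagonal")
    return d


def _kruskal_stress(d_emb: np.ndarray, disparities: np.ndarray) -> float:
    denom = (d_emb**2).sum()
    if denom == 0:
        return 0.0
    return float(np.sqrt(((d_emb - disparities) ** 2).sum() / denom))


def nmds(
    distances: pd.DataFrame | np.ndarray,
    k: int = 2,
    seed: int = 0,
    n_restarts: int = 20,
    max_iter: int = 300,
    tol: float = 1e-6,
) -> OrdinationResult:
    """Non-metric MDS by SMACOF majorization with isotonic disparities.

    Each restart initializes coordinates at random, then alternates a
    pool-adjacent-violators fit of disparities (monotone in the observed
    dissimilarities) with a Guttman-transform configuration update, until
    Kruskal stress-1 improves by less than *tol*.  The lowest-stress restart
    wins; coordinates are centered.  Bit-reproducible under *seed*.
    """
    d = _check_distances(distances)
    n = d.shape[0]
    if k < 1:
        raise ValueError("k must be >= 1")
    if k >= n:
        raise ValueError("k must be smaller than the number of samples")
    index = distances.index if isinstance(distances, pd.DataFrame) else pd.RangeIndex(n)

    iu = np.triu_indices(n, 1)
    diss = d[iu]
    order = np.argsort(diss, kind="stable")
    iso = IsotonicRegression()
    rng = np.random.default_rng(seed)

    best: tuple[float, np.ndarray, list[float]] | None = None
    for _ in range(n_restarts):
        x = rng.normal(size=(n, k))
        trace: list[float] = []
        stress_prev = np.inf
        for _ in range(max_iter):
            d_emb_flat = pdist(x)
            # monotone disparities in the order of the observed dissimilarities
            disp = np.empty_like(d_emb_flat)
            disp[order] = iso.fit_transform(np.arange(order.size), d_emb_flat[order])
            # scale so stress compares across iterations (Kruskal's convention)
            scale = np.sqrt((d_emb_flat**2).sum() / max((disp**2).sum(), 1e-300))
            disp *= scale
            stress = _kruskal_stress(d_emb_flat, disp)
            trace.append(stress)
            if stress_prev - stress < tol:
                break
            stress_prev = stress
            # Guttman transform
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = np.where(d_emb_flat > 0, disp / d_emb_flat, 0.0)
            b = -squareform(ratio)
            np.fill_diagonal(b, -b.sum(axis=1))
            x = b @ x / n
        if best is None or trace[-1] < best[0]:
            best = (trace[-1], x, trace)

    stress, x, trace = best
    x = x - x.mean(axis=0)
    coords = pd.DataFrame(x, index=index, columns=[f"NMDS{i+1}" for i in range(k)])
    return OrdinationResult(
        coordinates=coords,
        stress=stress,
        stress_trace=np.asarray(trace),
        seed=seed,
        n_iterations=len(trace),
    )


def permanova(
    distances: pd.DataFrame | np.ndarray,
    groups: Sequence,
    n_permutations: int = 9999,
    seed: int | None = None,
) -> PermanovaResult:
    """One-way PERMANOVA (Anderson's pseudo-F) on a distance matrix.

    Partitions the total sum of squared distances into between- and
    within-group parts; the p-value counts permuted statistics at least as
    large as the observed one, with the observed labelling included:
    p = (#{F_perm >= F} + 1) / (n_permutations + 1).
    """
    d = _check_distances(distances)
    labels = np.asarray(groups)
    n = d.shape[0]
    if labels.shape[0] != n:
        raise ValueError("one group label per sample required")
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ValueError("PERMANOVA needs at least two groups")
    if n_permutations < 1:
        raise ValueError("n_permutations must be positive")

    d2 = d**2
    sst = d2[np.triu_indices(n, 1)].sum() / n

    def pseudo_f(lab: np.ndarray) -> tuple[float, float]:
        ssw = 0.0
        for g in uniq:
            idx = np.flatnonzero(lab == g)
            if idx.size > 1:
                sub = d2[np.ix_(idx, idx)]
                ssw += sub[np.triu_indices(idx.size, 1)].sum() / idx.size
        ssb = sst - ssw
        f = (ssb / (uniq.size - 1)) / (ssw / (n - uniq.size))
        return f, ssb

    f_obs, ssb_obs = pseudo_f(labels)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        f_perm, _ = pseudo_f(rng.permutation(labels))
        if f_perm >= f_obs:
            hits += 1
    return PermanovaResult(
        r2=ssb_obs / sst,
        pseudo_f=f_obs,
        p_value=(hits + 1) / (n_permutations + 1),
        n_permutations=n_permutations,
    )


# ---------------------------------------------------------------------------
# family-level aggregation and group tests


def family_profile(
    table: pd.DataFrame,
    taxonomy: Mapping[str, str],
    top_n: int | None = None,
) -> pd.DataFrame:
    """Aggregate taxa to families and normalize to per-sample proportions.

    Taxa missing from *taxonomy* are pooled as ``Other``.  With *top_n*, only
    the families of highest mean abundance are kept and the rest pooled into
    ``Other`` as well; proportions sum to 1 per sample either way.
    """
    if not taxonomy:
        raise ValueError("taxonomy map is empty")
    families = [taxonomy.get(t, "Other") for t in table.columns]
    grouped = table.T.groupby(pd.Index(families, name="family")).sum().T
    totals = grouped.sum(axis=1)
    if (totals == 0).any():
        raise ValueError("a sample with zero total cannot be normalized")
    prop = grouped.div(totals, axis=0)
    if top_n is not None and top_n < prop.shape[1]:
        ranked = prop.mean(axis=0).drop(labels=["Other"], errors="ignore")
        keep = list(ranked.sort_values(ascending=False).index[:top_n])
        other = prop.drop(columns=keep).sum(axis=1)
        prop = prop[keep]
        prop["Other"] = other
    return prop


def group_difference(
    profile: pd.DataFrame,
    groups: Mapping[str, str] | pd.Series,
    group_a: str,
    group_b: str,
    confidence: float = 0.95,
) -> pd.DataFrame:
    """Per-family Welch t-test between two sample groups.

    Returns, per family, the difference of group means (B − A), its
    confidence interval and the two-sided p-value.  No multiplicity
    correction is applied; raw p-values are reported.
    """
    g = pd.Series(groups)
    idx_a = profile.index[g.reindex(profile.index) == group_a]
    idx_b = profile.index[g.reindex(profile.index) == group_b]
    if len(idx_a) < 2 or len(idx_b) < 2:
        raise ValueError("each group needs at least two samples")
    rows = {}
    for fam in profile.columns:
        a = profile.loc[idx_a, fam].to_numpy()
        b = profile.loc[idx_b, fam].to_numpy()
        res = stats.ttest_ind(b, a, equal_var=False)
        ci = res.confidence_interval(confidence)
        rows[fam] = {
            "mean_a": a.mean(),
            "mean_b": b.mean(),
            "mean_diff": b.mean() - a.mean(),
            "ci_low": ci.low,
            "ci_high": ci.high,
            "t": res.statistic,
            "p_value": res.pvalue,
        }
    return pd.DataFrame.from_dict(rows, orient="index")
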