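"""Expression quantification, clustering, replicate QC, DE, enrichment, qPCR.

FPKM normalization, low-expression filtering, MAD-based gene selection,
correlation-distance hierarchical clustering, bootstrap co-clustering QC of
replicate libraries, a lightweight negative-binomial Wald test for
differential expression, hypergeometric term enrichment with
Benjamini-Hochberg adjustment, and 2^-dCT qPCR quantification.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform


@dataclass
class CountMatrix:
    """Genes x libraries raw integer counts with optional effective lengths."""

    genes: list[str]
    libraries: list[str]
    counts: np.ndarray
    lengths: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.genes), len(self.libraries)):
            raise ValueError("counts shape does not match gene/library lists")
        if (self.counts < 0).any():
            raise ValueError("counts must be nonnegative")
        if self.lengths is not None:
            self.lengths = np.asarray(self.lengths, float)
            if self.lengths.shape != (len(self.genes),):
                raise ValueError("lengths shape does not match gene list")
            if (self.lengths <= 0).any():
                raise ValueError("gene lengths must be positive")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.genes, columns=self.libraries)


@dataclass
class ExpressionMatrix:
    """Real-valued genes x libraries matrix tagged with its scale."""

    genes: list[str]
    libraries: list[str]
    values: np.ndarray
    scale: str  # {fpkm, log2fpkm}

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genes, columns=self.libraries)


@dataclass
class ClusterResult:
    assignments: dict[str, int]
    linkage: np.ndarray
    genes: list[str]
    k: int

    def mean_profiles(self, em: ExpressionMatrix) -> pd.DataFrame:
        df = em.to_dataframe().loc[self.genes]
        lab = pd.Series(self.assignments)
        return df.groupby(lab).mean()


@dataclass
class QcResult:
    support: dict[str, float]
    flagged: list[str]


# ---------------------------------------------------------------------------
# Quantification

def fpkm(cm: CountMatrix) -> ExpressionMatrix:
    """FPKM(g,l) = counts(g,l) * 1e9 / (length(g) * total(l))."""
    if cm.lengths is None:
        raise ValueError("FPKM needs per-gene effective lengths")
    totals = cm.counts.sum(axis=0).astype(float)
    for lib, t in zip(cm.libraries, totals):
        if t == 0:
            raise ValueError(f"library {lib!r} has zero total counts")
    vals = cm.counts * 1e9 / (cm.lengths[:, None] * totals[None, :])
    return ExpressionMatrix(list(cm.genes), list(cm.libraries), vals, "fpkm")


def log2_fpkm(cm_or_em) -> ExpressionMatrix:
    """log2(FPKM + 1); the pseudocount keeps zeros finite and nonnegative."""
    em = fpkm(cm_or_em) if isinstance(cm_or_em, CountMatrix) else cm_or_em
    if em.scale != "fpkm":
        raise ValueError("log2_fpkm expects an FPKM-scale matrix")
    return ExpressionMatrix(
        list(em.genes), list(em.libraries), np.log2(em.values + 1.0), "log2fpkm"
    )


def filter_low(cm: CountMatrix, min_mean: float = 1.0) -> CountMatrix:
    """Keep genes with mean count across libraries >= min_mean."""
    keep = cm.counts.mean(axis=1) >= min_mean
    return CountMatrix(
        genes=[g for g, k in zip(cm.genes, keep) if k],
        libraries=list(cm.libraries),
        counts=cm.counts[keep],
        lengths=None if cm.lengths is None else cm.lengths[keep],
    )


def mad_select(em: ExpressionMatrix, top_n: int = 4000) -> list[str]:
    """Top genes by per-gene median absolute deviation across libraries.

    The MAD is unscaled (no 1.4826 consistency constant): only the ranking
    matters.  Ties are broken by gene id so selections are reproducible.
    """
    med = np.median(em.values, axis=1, keepdims=True)
    mad = np.median(np.abs(em.values - med), axis=1)
    if top_n > len(em.genes):
        warnings.warn(
            f"top_n={top_n} exceeds the {len(em.genes)} available genes; keeping all"
        )
        top_n = len(em.genes)
    order = sorted(range(len(em.genes)), key=lambda i: (-mad[i], em.genes[i]))
    return [em.genes[i] for i in order[:top_n]]


def subset(em: ExpressionMatrix, genes: Sequence[str]) -> ExpressionMatrix:
    idx = {g: i for i, g in enumerate(em.genes)}
    rows = [idx[g] for g in genes]
    return ExpressionMatrix(list(genes), list(em.libraries), em.values[rows], em.scale)


# ---------------------------------------------------------------------------
# Clustering

def correlation_distance(values: np.ndarray, ids: Sequence[str]) -> np.ndarray:
    """d(i,j) = 1 - Pearson r between rows; symmetric, zero diagonal, [0,2]."""
    values = np.asarray(values, float)
    sd = values.std(axis=1)
    for i, s in enumerate(sd):
        if s == 0:
            raise ValueError(f"profile {ids[i]!r} is constant; correlation undefined")
    r = np.corrcoef(values)
    d = 1.0 - r
    d = np.clip((d + d.T) / 2.0, 0.0, 2.0)
    np.fill_diagonal(d, 0.0)
    return d


def hcluster_cut(
    distance: np.ndarray, ids: Sequence[str], k: int, method: str = "complete"
) -> ClusterResult:
    """Agglomerative clustering of a precomputed distance matrix, cut at k.

    Labels are renumbered 1..k in order of first appearance so the result
    is deterministic for a fixed input.
    """
    n = len(ids)
    if not (1 <= k <= n):
        raise ValueError(f"k={k} out of range for {n} items")
    Z = hierarchy.linkage(squareform(distance, checks=False), method=method)
    raw = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    relabel: dict[int, int] = {}
    assignments = {}
    for i, lab in enumerate(raw):
        if lab not in relabel:
            relabel[lab] = len(relabel) + 1
        assignments[ids[i]] = relabel[lab]
    return ClusterResult(assignments=assignments, linkage=Z, genes=list(ids),
                         k=len(relabel))


def linkage_to_newick(Z: np.ndarray, ids: Sequence[str]) -> str:
    """Dendrogram export as a Newick string."""
    tree = hierarchy.to_tree(Z)

    def rec(node):
        if node.is_leaf():
            return ids[node.id]
        return f"({rec(node.left)},{rec(node.right)}):{node.dist:.6g}"

    return rec(tree) + ";"


# ---------------------------------------------------------------------------
# Bootstrap replicate QC

def bootstrap_replicate_qc(
    em: ExpressionMatrix,
    replicate_groups: Mapping[str, str],
    n_boot: int = 1000,
    min_support: float = 0.5,
    rng: Optional[np.random.Generator] = None,
    seed: Optional[int] = None,
) -> QcResult:
    """Flag replicate libraries that fail to co-cluster with their group.

    For each bootstrap (genes resampled with replacement) libraries are
    clustered by correlation distance + complete linkage.  A library
    co-clusters with its group in one bootstrap when, walking up the merge
    tree from the library's leaf, a same-group replicate appears while the
    cluster still has at most the group's size members -- i.e. the library
    joins a replicate before outside libraries pile in.  (A library that
    merges last into the all-library cluster trivially meets its
    replicates there, which must not count.)  Support is the fraction of
    bootstraps with co-clustering; libraries below min_support are flagged.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    if n_boot < 100:
        warnings.warn("n_boot < 100 gives coarse support estimates")
    libs = list(em.libraries)
    groups = {lib: replicate_groups[lib] for lib in libs}
    sizes: dict[str, int] = {}
    for g in groups.values():
        sizes[g] = sizes.get(g, 0) + 1
    for g, s in sizes.items():
        if s < 2:
            raise ValueError(f"replicate group {g!r} has a single library")
    if rng is None:
        rng = np.random.default_rng(seed if seed is not None else 0)

    X = em.values  # genes x libraries
    G, n = X.shape
    hits = np.zeros(n)
    group_idx = [
        [j for j in range(n) if groups[libs[j]] == groups[libs[i]] and j != i]
        for i in range(n)
    ]
    for _ in range(n_boot):
        rows = rng.integers(0, G, G)
        B = X[rows]
        sd = B.std(axis=0)
        sd[sd == 0] = 1.0  # degenerate bootstrap column: treat as uncorrelated
        r = np.corrcoef(B, rowvar=False)
        r = np.nan_to_num(r, nan=0.0)
        d = np.clip(1.0 - r, 0.0, 2.0)
        np.fill_diagonal(d, 0.0)
        d = (d + d.T) / 2.0
        Z = hierarchy.linkage(squareform(d, checks=False), method="complete")
        members: dict[int, set[int]] = {i: {i} for i in range(n)}
        done = [False] * n
        for mi, (a, b, _, _) in enumerate(Z):
            merged = members[int(a)] | members[int(b)]
            members[n + mi] = merged
            for i in merged:
                if done[i]:
                    continue
                if any(j in merged for j in group_idx[i]):
                    done[i] = True
                    if len(merged) <= sizes[groups[libs[i]]]:
                        hits[i] += 1
    support = {libs[i]: hits[i] / n_boot for i in range(n)}
    flagged = [lib for lib in libs if support[lib] < min_support]
    return QcResult(support=support, flagged=flagged)


# ---------------------------------------------------------------------------
# Differential expression (lightweight NB Wald stand-in)

def size_factors(counts: np.ndarray) -> np.ndarray:
    """Median-of-ratios library size factors."""
    with np.errstate(divide="ignore"):
        logs = np.log(counts.astype(float))
    finite = np.isfinite(logs).all(axis=1)
    if finite.sum() == 0:
        totals = counts.sum(axis=0).astype(float)
        return totals / np.exp(np.mean(np.log(totals)))
    ref = logs[finite].mean(axis=1)
    sf = np.exp(np.median(logs[finite] - ref[:, None], axis=0))
    return sf


def de_test(
    cm: CountMatrix, group_a: Sequence[str], group_b: Sequence[str]
) -> pd.DataFrame:
    """Per-gene log2 fold change (B over A), Wald p-value and BH-adjusted p.

    Size factors are median-of-ratios; the per-gene NB dispersion is a
    method-of-moments estimate floored at the across-gene median (the floor
    tames noisy small-sample estimates); the test is a normal-approximation
    Wald test on the log fold change of size-factor-normalized means.
    """
    ia = [cm.libraries.index(l) for l in group_a]
    ib = [cm.libraries.index(l) for l in group_b]
    if len(ia) < 2 or len(ib) < 2:
        raise ValueError("need >= 2 libraries per group")
    sub = cm.counts[:, ia + ib].astype(float)
    sf = size_factors(sub)
    norm = sub / sf[None, :]
    A, B = norm[:, : len(ia)], norm[:, len(ia):]
    mu_a, mu_b = A.mean(axis=1), B.mean(axis=1)
    var_a, var_b = A.var(axis=1, ddof=1), B.var(axis=1, ddof=1)

    with np.errstate(divide="ignore", invalid="ignore"):
        alpha_g = 0.5 * (
            np.where(mu_a > 0, (var_a - mu_a) / mu_a**2, 0.0)
            + np.where(mu_b > 0, (var_b - mu_b) / mu_b**2, 0.0)
        )
    alpha_g = np.clip(np.nan_to_num(alpha_g), 0.0, None)
    informative = (mu_a + mu_b) / 2 >= 5
    alpha0 = float(np.median(alpha_g[informative])) if informative.any() else 0.01
    alpha = np.maximum(alpha_g, alpha0)

    lfc = np.log2((mu_b + 0.5) / (mu_a + 0.5))
    var_ln_a = 1.0 / (len(ia) * (mu_a + 0.5)) + alpha / len(ia)
    var_ln_b = 1.0 / (len(ib) * (mu_b + 0.5)) + alpha / len(ib)
    se_ln = np.sqrt(var_ln_a + var_ln_b)
    z = lfc * np.log(2.0) / se_ln
    p = 2.0 * stats.norm.sf(np.abs(z))
    both_zero = (sub.sum(axis=1) == 0)
    lfc[both_zero] = 0.0
    p[both_zero] = 1.0
    padj = stats.false_discovery_control(p)
    return pd.DataFrame(
        {
            "gene": cm.genes,
            "base_mean_a": mu_a,
            "base_mean_b": mu_b,
            "log2fc": lfc,
            "p": p,
            "padj": padj,
        }
    ).set_index("gene")


def apply_thresholds(
    de: pd.DataFrame, p: float = 0.01, fc: float = 2.0
) -> set[str]:
    """DE call: |log2FC| >= log2(fc) AND p < cutoff."""
    mask = (de["p"] < p) & (de["log2fc"].abs() >= np.log2(fc))
    return set(de.index[mask])


# ---------------------------------------------------------------------------
# Enrichment

def enrich(
    gene_set: Iterable[str],
    term_annotation: Mapping[str, Iterable[str]],
    background: Iterable[str],
) -> pd.DataFrame:
    """Hypergeometric upper-tail enrichment per term, BH-adjusted.

    p = P(X >= k) with N = |background|, K = |term ∩ background|,
    n = |gene_set|, k = |term ∩ gene_set|.
    """
    bg = set(background)
    if not bg:
        raise ValueError("background must be nonempty")
    gs = set(gene_set)
    if not gs <= bg:
        raise ValueError("gene_set must be a subset of the background")
    rows = []
    for term in sorted(term_annotation):
        members = set(term_annotation[term]) & bg
        k = len(members & gs)
        K, n, N = len(members), len(gs), len(bg)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append((term, k, K, n, N, min(p, 1.0)))
    df = pd.DataFrame(rows, columns=["term", "k", "K", "n", "N", "p"]).set_index("term")
    df["padj"] = stats.false_discovery_control(df["p"]) if len(df) else []
    return df


# ---------------------------------------------------------------------------
# qPCR

def delta_ct(ct_table: pd.DataFrame, reference_genes: Sequence[str]) -> pd.DataFrame:
    """Relative expression by the 2^-dCT method.

    Technical replicate CTs are averaged first; dCT = CT_target - mean CT of
    the reference genes in the same sample; expression = 2^-dCT.
    """
    mean_ct = ct_table.groupby(["sample", "gene"])["ct"].mean().reset_index()
    rows = []
    for sample, grp in mean_ct.groupby("sample"):
        by_gene = dict(zip(grp["gene"], grp["ct"]))
        missing = [g for g in reference_genes if g not in by_gene]
        if missing:
            raise ValueError(
                f"sample {sample!r}: missing reference CT for {missing}"
            )
        ref = float(np.mean([by_gene[g] for g in reference_genes]))
        for gene, ct in by_gene.items():
            if gene in reference_genes:
                continue
            d = ct - ref
            rows.append((sample, gene, d, 2.0 ** (-d)))
    return pd.DataFrame(rows, columns=["sample", "gene", "delta_ct", "expression"])
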