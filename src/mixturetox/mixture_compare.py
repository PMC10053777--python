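"""Cross-mixture transcriptional comparison.

Quantifies how similarly two (or more) exposures perturb the transcriptome:
direction-concordance counts over the union of differentially expressed
genes, a through-the-origin regression of one mixture's log2 fold changes on
the other's (the slope is the relative transcriptional potency), k-means
gene clustering plus hierarchical treatment ordering for heatmaps, and PCA
of treatments in DEG log2FC space.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from sklearn.cluster import KMeans

from .diffexpr import ContrastResult, DegSet

__all__ = [
    "LfcMatrix",
    "build_lfc_matrix",
    "direction_concordance",
    "origin_regression",
    "heatmap_structure",
    "pca_treatments",
]


@dataclass
class LfcMatrix:
    """Gene x treatment log2FC values on the union of DEGs.

    Each row met the DEG threshold in at least one source contrast. NaN
    marks a gene that was untestable in a treatment; ``filled(0)`` renders
    those as "no measured change" for clustering.
    """

    values: pd.DataFrame
    lfc_min: float
    padj_max: float

    def __post_init__(self):
        if self.values.shape[1] < 2:
            raise ValueError("LfcMatrix needs >= 2 treatments")

    def filled(self, fill: float = 0.0) -> pd.DataFrame:
        return self.values.fillna(fill)


def build_lfc_matrix(
    contrasts: dict[str, ContrastResult],
    lfc_min: float = 1.0,
    padj_max: float = 0.05,
) -> LfcMatrix:
    """Union-of-DEGs log2FC matrix across the given contrasts."""
    from .diffexpr import classify_degs

    if len(contrasts) < 2:
        raise ValueError("need at least two contrasts")
    union: set = set()
    for name, c in contrasts.items():
        union |= set(classify_degs(c, lfc_min, padj_max).genes)
    genes = sorted(union)
    data = {name: c.table["log2FC"].reindex(genes) for name, c in contrasts.items()}
    return LfcMatrix(values=pd.DataFrame(data, index=genes), lfc_min=lfc_min, padj_max=padj_max)


def direction_concordance(
    contrast_a: ContrastResult,
    contrast_b: ContrastResult,
    union_degs: DegSet | None = None,
    *,
    deg_a: DegSet | None = None,
    deg_b: DegSet | None = None,
    lfc_min: float = 1.0,
    padj_max: float = 0.05,
) -> dict:
    """Count direction-discordant genes over the union of two DEG sets.

    A gene is discordant when its log2FC signs differ between the contrasts
    (both nonzero); "discordant and significant in both" additionally
    requires DEG membership in both contrasts. Genes of the union missing
    from either table count as non-discordant and are reported.
    """
    from .diffexpr import classify_degs

    if deg_a is None:
        deg_a = classify_degs(contrast_a, lfc_min, padj_max)
    if deg_b is None:
        deg_b = classify_degs(contrast_b, lfc_min, padj_max)
    union = set(union_degs.genes) if union_degs is not None else set(deg_a.genes) | set(deg_b.genes)

    a = contrast_a.table["log2FC"]
    b = contrast_b.table["log2FC"]
    n_missing = 0
    n_disc = 0
    n_disc_both = 0
    discordant_genes = []
    for g in union:
        if g not in a.index or g not in b.index or pd.isna(a[g]) or pd.isna(b[g]):
            n_missing += 1
            continue
        if a[g] * b[g] < 0:
            n_disc += 1
            discordant_genes.append(g)
            if g in deg_a and g in deg_b:
                n_disc_both += 1
    return {
        "n_union": len(union),
        "n_discordant": n_disc,
        "n_discordant_both_significant": n_disc_both,
        "n_missing": n_missing,
        "discordant_genes": sorted(discordant_genes),
    }


def origin_regression(x, y) -> dict:
    """Least-squares line through the origin, y = b*x.

    Returns the slope ``b = sum(xy)/sum(x^2)``, its 95% CI from
    ``SE = sqrt(RSS/(n-1) / sum(x^2))`` with a t(n-1) reference, and the
    no-intercept coefficient of determination ``r2 = 1 - RSS/sum(y^2)``.
    Pairs with a missing value are dropped and counted.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    ok = np.isfinite(x) & np.isfinite(y)
    n_dropped = int((~ok).sum())
    x, y = x[ok], y[ok]
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 paired finite values")
    sxx = float(np.sum(x * x))
    if sxx == 0:
        raise ValueError("x is all zero; slope through the origin is undefined")
    b = float(np.sum(x * y)) / sxx
    rss = float(np.sum((y - b * x) ** 2))
    se = np.sqrt(rss / (n - 1) / sxx)
    tcrit = stats.t.ppf(0.975, n - 1)
    syy = float(np.sum(y * y))
    r2 = 1.0 - rss / syy if syy > 0 else np.nan
    return {
        "slope": b,
        "se": float(se),
        "ci95": (b - tcrit * se, b + tcrit * se),
        "r2": float(r2),
        "n": n,
        "n_dropped": n_dropped,
    }


def heatmap_structure(
    lfc: LfcMatrix,
    k: int = 8,
    starts: int = 500,
    seed: int = 0,
) -> dict:
    """Row (gene) k-means and column (treatment) hierarchical structure.

    Genes are partitioned by the best of ``starts`` Lloyd's k-means runs
    (lowest within-cluster sum of squares; each start seeded from a stream
    spawned off the master seed, so enlarging ``starts`` only adds runs).
    Treatments are ordered by average-linkage hierarchical clustering on
    Euclidean distances between treatment columns. Missing log2FC values are
    rendered as 0 before clustering.
    """
    X = lfc.filled(0.0)
    n_genes, n_trt = X.shape
    if k >= n_genes:
        raise ValueError(f"k={k} must be < number of genes ({n_genes})")
    if starts < 1:
        raise ValueError("starts must be >= 1")
    arr = X.to_numpy()

    seeds = np.random.SeedSequence(seed).generate_state(starts) % (2**31)
    best = None
    for s in seeds:
        km = KMeans(n_clusters=k, init="random", n_init=1, algorithm="lloyd", random_state=int(s))
        km.fit(arr)
        if best is None or km.inertia_ < best.inertia_:
            best = km
    labels = pd.Series(best.labels_, index=X.index, name="cluster")

    if n_trt > 2:
        Z = hierarchy.linkage(pdist(arr.T, metric="euclidean"), method="average")
        order = list(hierarchy.leaves_list(Z))
    else:
        Z = None
        order = list(range(n_trt))
    treatment_order = [X.columns[i] for i in order]

    summaries = (
        X.abs()
        .groupby(labels)
        .mean()
        .rename_axis(index="cluster")
        .rename(columns=lambda c: f"mean_abs_lfc_{c}")
    )
    summaries["n_genes"] = labels.value_counts().sort_index()
    return {
        "gene_cluster_labels": labels,
        "treatment_order": treatment_order,
        "cluster_summaries": summaries,
        "best_wss": float(best.inertia_),
        "linkage": Z,
    }


def pca_treatments(lfc: LfcMatrix) -> dict:
    """PCA of treatments in gene log2FC space (centered, not scaled).

    Rows of the analyzed matrix are treatments, features are genes; missing
    values are rendered as 0. Variance fractions are eigenvalue shares and
    sum to 1 over all components.
    """
    X = lfc.filled(0.0).to_numpy().T  # treatments x genes
    n_trt = X.shape[0]
    if n_trt < 3:
        raise ValueError("pca_treatments needs >= 3 treatments")
    Xc = X - X.mean(axis=0, keepdims=True)
    if np.allclose(Xc, 0):
        raise ValueError("constant log2FC matrix; PCA undefined")
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    var = s**2
    frac = var / var.sum()
    coords = U * s
    names = list(lfc.values.columns)
    coord_df = pd.DataFrame(
        coords,
        index=pd.Index(names, name="treatment"),
        columns=[f"PC{i + 1}" for i in range(coords.shape[1])],
    )
    return {"coordinates": coord_df, "variance_fractions": frac}
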