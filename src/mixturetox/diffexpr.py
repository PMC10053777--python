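"""Outlier screening and negative-binomial differential expression.

The DE model is the two-group NB GLM with log link, a per-sample offset
(log size factor, median-of-ratios), and a single dispersion shared by all
genes and treatment groups: ``var = mu + alpha * mu**2``. The treatment
coefficient is tested with a Wald z statistic and p-values are BH-adjusted
within each contrast. Sample-level quality screening uses classical
multidimensional scaling of log2(CPM+1) with a robust within-group distance
rule.

This is a deliberate simplification of full DESeq2 machinery: no per-gene
or trended dispersions, no LFC shrinkage, no independent filtering, no
count-outlier replacement. With a design this simple the group-mean MLEs
have a closed fixed-point form, so the fit is vectorized across all genes.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize_scalar
from scipy.spatial.distance import pdist, squareform
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CountMatrix",
    "ContrastResult",
    "DegSet",
    "classical_mds",
    "mds_screen",
    "size_factors",
    "estimate_common_dispersion",
    "nb_wald_contrast",
    "classify_degs",
    "read_contrast_tsv",
    "write_contrast_tsv",
]

#: |log2FC| cutoffs used in the study: 1.0 for heatmaps/PCA, 0.5 for GO queries.
LFC_STRICT = 1.0
LFC_RELAXED = 0.5
PADJ_DEFAULT = 0.05


@dataclass
class CountMatrix:
    """Integer gene x sample counts with per-sample group labels."""

    counts: pd.DataFrame
    groups: pd.Series

    def __post_init__(self):
        c = self.counts
        if c.index.has_duplicates:
            raise ValueError("duplicate gene ids in count matrix")
        if c.columns.has_duplicates:
            raise ValueError("duplicate sample ids in count matrix")
        missing = set(c.columns) - set(self.groups.index)
        if missing:
            raise ValueError(f"samples without a group label: {sorted(missing)}")
        self.groups = self.groups.loc[c.columns]
        vals = c.to_numpy()
        if np.any(vals < 0):
            raise ValueError("counts must be nonnegative")
        if not np.allclose(vals, np.round(vals)):
            raise ValueError("counts must be integral")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def group_names(self) -> list[str]:
        return list(dict.fromkeys(self.groups))

    def subset_samples(self, samples) -> "CountMatrix":
        return CountMatrix(self.counts[list(samples)], self.groups.loc[list(samples)])

    def drop_samples(self, samples) -> "CountMatrix":
        keep = [s for s in self.counts.columns if s not in set(samples)]
        return self.subset_samples(keep)


@dataclass
class ContrastResult:
    """Per-gene statistics for one treatment-vs-control contrast.

    ``table`` is indexed by gene id with columns base_mean, log2FC,
    wald_stat, p, p_adj; genes untestable (all-zero in both groups) carry
    NaN and are excluded from the BH family.
    """

    treatment: str
    control: str
    table: pd.DataFrame

    def __post_init__(self):
        required = {"log2FC", "wald_stat", "p", "p_adj"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"contrast table missing columns {required - set(self.table.columns)}")

    def tested_genes(self) -> pd.Index:
        """Genes with a defined test result (the ORA background universe)."""
        return self.table.index[self.table["p"].notna()]


@dataclass
class DegSet:
    """Genes passing |log2FC| >= lfc_min and p_adj <= padj_max in one contrast."""

    genes: frozenset
    direction: dict = field(default_factory=dict)  # gene -> +1 / -1
    lfc_min: float = LFC_STRICT
    padj_max: float = PADJ_DEFAULT
    source: str = ""

    def __len__(self):
        return len(self.genes)

    def __contains__(self, g):
        return g in self.genes

    def up(self) -> set:
        return {g for g, d in self.direction.items() if d > 0}

    def down(self) -> set:
        return {g for g, d in self.direction.items() if d < 0}


def log_cpm(counts: pd.DataFrame, prior: float = 1.0) -> pd.DataFrame:
    """log2(counts-per-million + prior)."""
    lib = counts.sum(axis=0).astype(float)
    if (lib == 0).any():
        raise ValueError("sample with zero total counts")
    return np.log2(counts.div(lib, axis=1) * 1e6 + prior)


def classical_mds(D: np.ndarray, dims: int = 2) -> np.ndarray:
    """Classical (Torgerson) MDS of a distance matrix.

    Eigendecomposition of the double-centered squared-distance matrix;
    returns point coordinates in ``dims`` dimensions (negative eigenvalues
    are clipped to zero). A Euclidean distance matrix of points in
    ``dims``-space is recovered exactly up to rotation/reflection.
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if D.shape != (n, n):
        raise ValueError("D must be square")
    if dims >= n:
        raise ValueError(f"dims={dims} must be < number of points ({n})")
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    evals, evecs = np.linalg.eigh(B)
    order = np.argsort(evals)[::-1][:dims]
    lam = np.clip(evals[order], 0.0, None)
    return evecs[:, order] * np.sqrt(lam)


def mds_screen(cm: CountMatrix, dims: int = 2, mad_factor: float = 3.0) -> pd.DataFrame:
    """Classical MDS of samples with a robust within-group outlier flag.

    Samples are embedded by eigendecomposition of the double-centered
    squared Euclidean distance matrix of log2(CPM+1). A sample is flagged
    when its embedded distance to its group centroid exceeds
    ``median + mad_factor * MAD`` of within-group centroid distances pooled
    across all groups. Flags are advisory; nothing is removed here.
    """
    if cm.n_samples < 3:
        raise ValueError("mds_screen needs at least 3 samples")
    if dims >= cm.n_samples:
        raise ValueError(f"dims={dims} must be < number of samples ({cm.n_samples})")
    X = log_cpm(cm.counts).to_numpy().T  # samples x genes
    D = squareform(pdist(X, metric="euclidean"))
    n = D.shape[0]
    coords = classical_mds(D, dims)

    samples = list(cm.counts.columns)
    grp = cm.groups.to_numpy()
    dist_centroid = np.zeros(n)
    for g in np.unique(grp):
        idx = np.where(grp == g)[0]
        centroid = coords[idx].mean(axis=0)
        dist_centroid[idx] = np.linalg.norm(coords[idx] - centroid, axis=1)
    med = np.median(dist_centroid)
    mad = stats.median_abs_deviation(dist_centroid)
    thresh = med + mad_factor * mad
    flags = dist_centroid > thresh if mad > 0 else np.zeros(n, dtype=bool)

    out = pd.DataFrame(
        {f"dim{i + 1}": coords[:, i] for i in range(dims)},
        index=pd.Index(samples, name="sample"),
    )
    out["group"] = grp
    out["dist_to_centroid"] = dist_centroid
    out["outlier_flag"] = flags
    return out


def size_factors(counts: pd.DataFrame, min_positive: int = 50) -> pd.Series:
    """Median-of-ratios size factors against the geometric-mean pseudo-reference.

    Falls back to library-size ratios (normalized to geometric mean 1) when
    fewer than ``min_positive`` genes have all-positive counts.
    """
    vals = counts.to_numpy(dtype=float)
    all_pos = np.all(vals > 0, axis=1)
    if all_pos.sum() >= min_positive:
        logs = np.log(vals[all_pos])
        ref = logs.mean(axis=1)  # log geometric mean per gene
        sf = np.exp(np.median(logs - ref[:, None], axis=0))
    else:
        lib = vals.sum(axis=0)
        if np.any(lib == 0):
            raise ValueError("sample with zero total counts")
        sf = lib / np.exp(np.mean(np.log(lib)))
    return pd.Series(sf, index=counts.columns, name="size_factor")


def _group_indices(cm: CountMatrix) -> dict[str, np.ndarray]:
    grp = cm.groups.to_numpy()
    return {g: np.where(grp == g)[0] for g in dict.fromkeys(grp)}


def _nb_loglik_terms(y: np.ndarray, mu: np.ndarray, alpha: float) -> np.ndarray:
    """Elementwise NB log-likelihood; entries with mu == 0 contribute 0."""
    out = np.zeros_like(mu, dtype=float)
    ok = mu > 0
    y, mu = y[ok], mu[ok]
    if alpha <= 0:
        out[ok] = y * np.log(mu) - mu - gammaln(y + 1)
        return out
    r = 1.0 / alpha
    out[ok] = (
        gammaln(y + r)
        - gammaln(r)
        - gammaln(y + 1)
        + r * np.log(r / (r + mu))
        + y * np.log(mu / (r + mu))
    )
    return out


def estimate_common_dispersion(
    cm: CountMatrix,
    sf: pd.Series | None = None,
    *,
    cox_reid: bool = True,
    bounds: tuple[float, float] = (1e-8, 10.0),
    grid_points: int = 40,
) -> float:
    """One NB dispersion alpha shared by every gene and treatment group.

    Maximizes the profile likelihood over all genes with group means plugged
    in, restricted to groups with at least two replicates (a group without
    replication carries no dispersion information once its mean is fitted).
    By default the likelihood carries the Cox-Reid adjustment
    ``-0.5 * sum_g log(sum_j w_j)`` that compensates for the fitted means —
    without it the shared-dispersion estimate is biased low at the small
    per-group sample sizes typical of these designs. Optimization is a
    log-scale grid scan followed by bounded refinement.
    """
    if sf is None:
        sf = size_factors(cm.counts)
    sfv = sf.loc[cm.counts.columns].to_numpy()
    y = cm.counts.to_numpy(dtype=float)
    groups = _group_indices(cm)
    rep_groups = {g: idx for g, idx in groups.items() if idx.size >= 2}
    if not rep_groups:
        raise ValueError("no group has >= 2 replicates; dispersion is not estimable")

    blocks = []  # (y_block, s_block, m_hat) per replicated group
    for g, idx in rep_groups.items():
        yb = y[:, idx]
        sb = sfv[idx]
        m = yb.sum(axis=1) / sb.sum()
        blocks.append((yb, sb, m))

    def neg_obj(log_alpha: float) -> float:
        a = float(np.exp(log_alpha))
        total = 0.0
        for yb, sb, m in blocks:
            mu = m[:, None] * sb[None, :]
            total += _nb_loglik_terms(yb, mu, a).sum()
            if cox_reid:
                w = mu / (1.0 + a * mu)
                ws = w.sum(axis=1)
                pos = ws > 0
                total -= 0.5 * np.log(ws[pos]).sum()
        return -total

    lo, hi = np.log(bounds[0]), np.log(bounds[1])
    grid = np.linspace(lo, hi, grid_points)
    vals = np.array([neg_obj(g) for g in grid])
    i = int(np.argmin(vals))
    g_lo = grid[max(i - 1, 0)]
    g_hi = grid[min(i + 1, grid_points - 1)]
    res = minimize_scalar(neg_obj, bounds=(g_lo, g_hi), method="bounded")
    alpha_hat = float(np.exp(res.x))
    # boundary means the data look (sub-)Poisson
    if i == 0 and neg_obj(lo) <= res.fun:
        alpha_hat = float(np.exp(lo))
    return alpha_hat


def _fit_group_means(y: np.ndarray, s: np.ndarray) -> np.ndarray:
    """Per-gene group mean parameter m (mean at size factor 1): sum(y)/sum(s).

    This is the exact NB GLM solution whenever size factors are equal within
    the group, and in general the quasi-Poisson estimating-equation solution;
    it makes fold changes exactly equivariant under rescaling counts and size
    factors together.
    """
    return y.sum(axis=1) / s.sum()


def nb_wald_contrast(
    cm: CountMatrix,
    treatment: str,
    control: str,
    alpha_hat: float,
    sf: pd.Series | None = None,
) -> ContrastResult:
    """Wald test of the treatment coefficient in a two-group NB GLM.

    The model is ``log mu_j = log s_j + b0 + b1 * [j in treatment]`` with
    dispersion ``alpha_hat``; b1 estimates the natural-log fold change, and
    its Wald variance is the sum of inverse Fisher informations of the two
    group log-means evaluated at the fitted means (total count over total
    size factor per group — the exact GLM solution for within-group-equal
    size factors). Genes detected in only one group get a half-count
    continuity correction on both group totals (for the reported log2FC and
    for evaluating the information); genes with zero counts everywhere are
    reported NaN and excluded from the BH family.
    """
    for g in (treatment, control):
        if g not in set(cm.groups):
            raise ValueError(f"group {g!r} not present in count matrix")
    if alpha_hat < 0:
        raise ValueError("alpha_hat must be >= 0")
    if sf is None:
        sf = size_factors(cm.counts)
    sfv = sf.loc[cm.counts.columns].to_numpy()
    groups = _group_indices(cm)
    y = cm.counts.to_numpy(dtype=float)

    res = {}
    for g in (control, treatment):
        idx = groups[g]
        yb, sb = y[:, idx], sfv[idx]
        m = _fit_group_means(yb, sb)
        # continuity correction applied below only where a group is all-zero
        m_pseudo = (yb.sum(axis=1) + 0.5) / sb.sum()
        res[g] = (m, m_pseudo, sb)

    m_c, mp_c, s_c = res[control]
    m_t, mp_t, s_t = res[treatment]
    both_zero = (m_c == 0) & (m_t == 0)
    one_zero = ((m_c == 0) | (m_t == 0)) & ~both_zero
    m_c_eff = np.where(one_zero, mp_c, m_c)
    m_t_eff = np.where(one_zero, mp_t, m_t)

    with np.errstate(divide="ignore", invalid="ignore"):
        lfc = np.log2(m_t_eff) - np.log2(m_c_eff)
        info_c = _fisher_info(m_c_eff, s_c, alpha_hat)
        info_t = _fisher_info(m_t_eff, s_t, alpha_hat)
        se = np.sqrt(1.0 / info_c + 1.0 / info_t)  # natural-log scale
        beta = np.log(m_t_eff) - np.log(m_c_eff)
        z = beta / se
    z = np.where(beta == 0, 0.0, z)
    p = 2.0 * stats.norm.sf(np.abs(z))

    lfc[both_zero] = np.nan
    z[both_zero] = np.nan
    p[both_zero] = np.nan

    p_adj = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    if ok.any():
        p_adj[ok] = multipletests(p[ok], method="fdr_bh")[1]

    base_mean = (y / sfv[None, :]).mean(axis=1)
    table = pd.DataFrame(
        {"base_mean": base_mean, "log2FC": lfc, "wald_stat": z, "p": p, "p_adj": p_adj},
        index=cm.counts.index.rename("gene_id"),
    )
    return ContrastResult(treatment=treatment, control=control, table=table)


def _fisher_info(m: np.ndarray, s: np.ndarray, alpha: float) -> np.ndarray:
    """Fisher information of a group's log-mean: sum_j mu_j / (1 + alpha mu_j)."""
    mu = m[:, None] * s[None, :]
    return (mu / (1.0 + alpha * mu)).sum(axis=1)


def classify_degs(
    contrast: ContrastResult,
    lfc_min: float = LFC_STRICT,
    padj_max: float = PADJ_DEFAULT,
) -> DegSet:
    """Genes with |log2FC| >= lfc_min and p_adj <= padj_max, with direction."""
    if lfc_min < 0 or not 0 < padj_max <= 1:
        raise ValueError("thresholds must satisfy lfc_min >= 0 and 0 < padj_max <= 1")
    t = contrast.table
    hit = (t["log2FC"].abs() >= lfc_min) & (t["p_adj"] <= padj_max)
    hit = hit.fillna(False)
    genes = frozenset(t.index[hit])
    direction = {g: (1 if t.at[g, "log2FC"] > 0 else -1) for g in genes}
    return DegSet(
        genes=genes,
        direction=direction,
        lfc_min=lfc_min,
        padj_max=padj_max,
        source=f"{contrast.treatment}_vs_{contrast.control}",
    )


def write_contrast_tsv(contrast: ContrastResult, path: str | os.PathLike) -> None:
    contrast.table.sort_index().to_csv(path, sep="\t", index_label="gene_id")


def read_contrast_tsv(
    path: str | os.PathLike, treatment: str = "treatment", control: str = "control"
) -> ContrastResult:
    """Read a per-gene contrast table (gene_id, log2FC, p_adj at minimum).

    Accepts the pipeline's own output as well as published per-gene tables;
    common column aliases (log2FoldChange, padj, pvalue, stat) are mapped.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    aliases = {
        "log2FoldChange": "log2FC",
        "log2fc": "log2FC",
        "padj": "p_adj",
        "pvalue": "p",
        "p_value": "p",
        "stat": "wald_stat",
        "baseMean": "base_mean",
    }
    df = df.rename(columns=aliases)
    if "log2FC" not in df.columns or "p_adj" not in df.columns:
        raise ValueError("contrast table needs log2FC and p_adj columns")
    for col in ("p", "wald_stat"):
        if col not in df.columns:
            df[col] = np.nan
    return ContrastResult(treatment=treatment, control=control, table=df)
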