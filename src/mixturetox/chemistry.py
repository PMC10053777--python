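"""PAH chemistry summaries for passive-sampler extract characterization.

Concentration tables are tidy: one row per (analyte, sample, replicate)
with concentration in uM at the 1% exposure scale. Summaries are the total
PAH concentration with a propagated t-based confidence interval, the
source-diagnostic ratios FLA/PYR, RET/CHR and PHE/ANT used to compare
contamination signatures between sites, and the per-analyte composition
profile.

Replicate variance may come from the sample itself or, when only one site
was measured in replicate, be transferred from a designated reference
sample via per-analyte coefficients of variation (so the uncertainty scales
with the concentration it is attached to).
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PAH_PANEL",
    "DIAGNOSTIC_RATIOS",
    "sum_pah",
    "diagnostic_ratios",
    "composition_profile",
]

DIAGNOSTIC_RATIOS = (("FLA", "PYR"), ("RET", "CHR"), ("PHE", "ANT"))


def _load_panel() -> list[str]:
    with resources.files("mixturetox.data").joinpath("pah_panel.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t", comment="#")
    return list(df["abbreviation"])


#: The 33-analyte quantitative PAH panel (abbreviations).
PAH_PANEL: list[str] = _load_panel()

_REQ = {"analyte", "sample", "concentration"}


def _check(records: pd.DataFrame) -> pd.DataFrame:
    if not _REQ.issubset(records.columns):
        raise ValueError(f"chemistry table needs columns {_REQ}")
    if (records["concentration"] < 0).any():
        raise ValueError("concentrations must be >= 0")
    return records


def _analyte_stats(records: pd.DataFrame, sample: str) -> pd.DataFrame:
    block = records[records["sample"] == sample]
    if block.empty:
        raise KeyError(f"no records for sample {sample!r}")
    g = block.groupby("analyte")["concentration"]
    out = pd.DataFrame({"mean": g.mean(), "var": g.var(ddof=1), "n": g.count()})
    return out


def sum_pah(
    records: pd.DataFrame,
    sample: str,
    *,
    variance_sample: str | None = None,
    level: float = 0.95,
    loq: float = 0.0,
) -> dict:
    """Total PAH concentration of one sample with a propagated CI.

    The total is the sum of per-analyte replicate means; its variance is the
    sum of per-analyte variances of the mean (analytes assumed independent),
    and the CI uses a t quantile with df = replicates - 1. When the sample
    itself is unreplicated, ``variance_sample`` names a reference sample
    whose per-analyte CVs supply the relative uncertainty. Values below
    ``loq`` enter the total as 0 and are counted in ``n_below_loq``. With no
    variance source the total is returned with the CI flagged unavailable.
    """
    records = _check(records).copy()
    below = records["concentration"] < loq
    records.loc[below, "concentration"] = 0.0
    st = _analyte_stats(records, sample)
    total = float(st["mean"].sum())

    var_src = sample
    if st["n"].max() < 2:
        var_src = variance_sample
    if var_src is None:
        return {"total": total, "lo": np.nan, "hi": np.nan,
                "ci_available": False, "n_below_loq": int(below.sum())}
    vs = _analyte_stats(records, var_src)
    if vs["n"].max() < 2:
        raise ValueError(f"variance sample {var_src!r} has no replication")
    if var_src == sample:
        var_mean = (st["var"] / st["n"]).fillna(0.0)
        df = int(st["n"].max()) - 1
    else:
        # transfer relative uncertainty: sd scales with this sample's mean
        cv2 = (vs["var"] / vs["mean"] ** 2).replace([np.inf, -np.inf], np.nan)
        cv2 = cv2.reindex(st.index).fillna(0.0)
        var_mean = cv2 * st["mean"] ** 2 / vs["n"].reindex(st.index).fillna(1)
        df = int(vs["n"].max()) - 1
    se = float(np.sqrt(var_mean.sum()))
    tcrit = stats.t.ppf(0.5 + level / 2, df)
    return {
        "total": total,
        "lo": total - tcrit * se,
        "hi": total + tcrit * se,
        "se": se,
        "df": df,
        "ci_available": True,
        "n_below_loq": int(below.sum()),
    }


def diagnostic_ratios(
    records: pd.DataFrame,
    samples: list[str] | None = None,
    ratios: tuple = DIAGNOSTIC_RATIOS,
    *,
    loq: float = 0.0,
) -> pd.DataFrame:
    """Source-diagnostic concentration ratios per sample.

    Ratios are computed on replicate-mean concentrations; analytes at or
    below ``loq`` are excluded (a missing or sub-LOQ analyte flags that
    ratio as NaN, others are still returned). With exactly two samples a
    ``rel_diff`` column gives |r_A - r_B| / mean(r) per ratio — near-zero
    relative differences indicate a shared contamination source.
    """
    records = _check(records)
    if samples is None:
        samples = sorted(records["sample"].unique())
    out = {}
    for s in samples:
        means = _analyte_stats(records, s)["mean"]
        vals = {}
        for num, den in ratios:
            num_v = means.get(num, np.nan)
            den_v = means.get(den, np.nan)
            if not np.isfinite(num_v) or not np.isfinite(den_v) or den_v <= loq or num_v <= loq:
                vals[f"{num}/{den}"] = np.nan
            else:
                vals[f"{num}/{den}"] = num_v / den_v
        out[s] = vals
    df = pd.DataFrame(out)
    if len(samples) == 2:
        a, b = samples
        mean_r = (df[a] + df[b]) / 2
        df["rel_diff"] = (df[a] - df[b]).abs() / mean_r
    return df


def composition_profile(records: pd.DataFrame, sample: str) -> pd.Series:
    """Per-analyte proportion of the sample's total PAH (sums to 1)."""
    means = _analyte_stats(_check(records), sample)["mean"]
    total = means.sum()
    if total <= 0:
        raise ValueError(f"sample {sample!r} has zero total concentration")
    return (means / total).rename("proportion")
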