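"""Developmental-screen statistics for the zebrafish morphology assay.

Embryos are exposed in multiwell plates to a dilution series of each
mixture extract (40 fish per dose) alongside 8 negative- and 8 positive-
control fish per plate, and scored for binary endpoints (mortality, any
effect except mortality, wavy notochord, ...) at 24 and 120 hpf. This
module covers plate quality control, exact binomial incidence intervals,
and Fisher's exact comparisons between arms at a chosen dilution.
"""

from __future__ import annotations

import re
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "plate_qc",
    "extract_plate_controls",
    "incidence_ci",
    "fisher_compare",
    "endpoint_profile",
]

#: A plate fails QC when mortality exceeds this many fish in either control arm.
QC_MAX_CONTROL_DEATHS = 2


def plate_qc(control_mortality: pd.DataFrame) -> pd.DataFrame:
    """Pass/fail each plate on its control mortality.

    ``control_mortality`` has columns (plate, control_type, n_dead) with
    control_type in {negative, positive}. A plate fails — and is flagged for
    retest — iff mortality exceeds 2 fish in either the negative or the
    positive controls (2 dead is still a pass). A plate missing either
    control arm is an error.
    """
    req = {"plate", "control_type", "n_dead"}
    if not req.issubset(control_mortality.columns):
        raise ValueError(f"control table needs columns {req}")
    rows = []
    for plate, block in control_mortality.groupby("plate"):
        arms = dict(zip(block["control_type"], block["n_dead"]))
        if "negative" not in arms or "positive" not in arms:
            raise ValueError(f"plate {plate!r} is missing a control arm")
        failed = arms["negative"] > QC_MAX_CONTROL_DEATHS or arms["positive"] > QC_MAX_CONTROL_DEATHS
        rows.append(
            {
                "plate": plate,
                "neg_mortality": arms["negative"],
                "pos_mortality": arms["positive"],
                "pass": not failed,
                "retest": failed,
            }
        )
    return pd.DataFrame(rows).set_index("plate")


_CTRL_RE = re.compile(r"^control_(negative|positive)_plate(\w+)$")


def extract_plate_controls(records: pd.DataFrame) -> pd.DataFrame:
    """Pull per-plate control mortality rows out of a screen record table.

    Recognizes treatments named ``control_<type>_plate<id>`` with the
    mortality endpoint (the layout the synthetic generator emits).
    """
    rows = []
    for _, r in records.iterrows():
        m = _CTRL_RE.match(str(r["treatment"]))
        if m and r["endpoint"] == "mortality":
            rows.append({"plate": m.group(2), "control_type": m.group(1), "n_dead": r["n_affected"]})
    return pd.DataFrame(rows, columns=["plate", "control_type", "n_dead"])


def incidence_ci(
    n_affected: int, n_exposed: int, level: float = 0.95, method: str = "clopper-pearson"
) -> dict:
    """Incidence proportion with an exact (Clopper-Pearson) binomial CI.

    ``method="wilson"`` gives the Wilson score interval instead.
    """
    if n_exposed <= 0:
        raise ValueError("n_exposed must be > 0")
    if not 0 <= n_affected <= n_exposed:
        raise ValueError("need 0 <= n_affected <= n_exposed")
    ci_method = {"clopper-pearson": "beta", "wilson": "wilson"}.get(method)
    if ci_method is None:
        raise ValueError(f"unknown CI method {method!r}")
    lo, hi = proportion_confint(n_affected, n_exposed, alpha=1 - level, method=ci_method)
    return {"proportion": n_affected / n_exposed, "lo": float(lo), "hi": float(hi)}


def fisher_compare(a_affected: int, a_n: int, b_affected: int, b_n: int) -> float:
    """Two-sided Fisher's exact p for a 2x2 incidence comparison.

    Two-sidedness is by the probability-mass rule: sum over tables whose
    point hypergeometric probability does not exceed the observed table's.
    """
    table = [[a_affected, a_n - a_affected], [b_affected, b_n - b_affected]]
    if min(min(row) for row in table) < 0:
        raise ValueError("affected counts must be within [0, n]")
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def endpoint_profile(
    records: pd.DataFrame,
    dilution: float,
    *,
    control_label: str = "control",
    level: float = 0.95,
    adjust: bool = False,
) -> pd.DataFrame:
    """Per-endpoint incidence table at one dilution, with CIs and Fisher tests.

    For every endpoint and treatment present at the dilution: incidence with
    its exact CI, Fisher's exact p vs the control arm, and pairwise Fisher p
    between treatments. Rows are sorted by the largest incidence difference
    from control. ``adjust=True`` BH-adjusts each p-value family across
    endpoints (off by default; the primary screen comparison is a single
    unadjusted test).
    """
    req = {"treatment", "dilution", "endpoint", "n_exposed", "n_affected"}
    if not req.issubset(records.columns):
        raise ValueError(f"records need columns {req}")
    ctrl = records[records["treatment"] == control_label]
    if ctrl.empty:
        raise ValueError(f"no control records (treatment == {control_label!r})")
    at = records[np.isclose(records["dilution"].astype(float), dilution)]
    at = at[~at["treatment"].astype(str).str.startswith("control_")]
    at = at[at["treatment"] != control_label]
    if at.empty:
        raise ValueError(f"no treatment records at dilution {dilution}")
    treatments = sorted(at["treatment"].unique())

    def _arm(df, trt, ep):
        block = df[(df["treatment"] == trt) & (df["endpoint"] == ep)]
        if block.empty:
            return None
        return int(block["n_affected"].sum()), int(block["n_exposed"].sum())

    rows = []
    for ep in sorted(at["endpoint"].unique()):
        c = _arm(ctrl, control_label, ep)
        if c is None:
            continue
        rec = {"endpoint": ep, "control_incidence": c[0] / c[1]}
        max_diff = 0.0
        for trt in treatments:
            arm = _arm(at, trt, ep)
            if arm is None:
                rec[f"{trt}_incidence"] = np.nan
                continue
            ci = incidence_ci(arm[0], arm[1], level=level)
            rec[f"{trt}_incidence"] = ci["proportion"]
            rec[f"{trt}_lo"], rec[f"{trt}_hi"] = ci["lo"], ci["hi"]
            rec[f"{trt}_p_vs_control"] = fisher_compare(arm[0], arm[1], c[0], c[1])
            max_diff = max(max_diff, abs(ci["proportion"] - rec["control_incidence"]))
        for t1, t2 in combinations(treatments, 2):
            a1, a2 = _arm(at, t1, ep), _arm(at, t2, ep)
            if a1 and a2:
                rec[f"p_{t1}_vs_{t2}"] = fisher_compare(a1[0], a1[1], a2[0], a2[1])
        rec["max_abs_diff_vs_control"] = max_diff
        rows.append(rec)
    out = pd.DataFrame(rows).sort_values("max_abs_diff_vs_control", ascending=False)
    out = out.set_index("endpoint")
    if adjust:
        for col in out.columns:
            if col.startswith("p_") or col.endswith("_p_vs_control"):
                ok = out[col].notna()
                out.loc[ok, col] = multipletests(out.loc[ok, col], method="fdr_bh")[1]
    return out
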