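"""Descriptive tables: mortality rates by disclosed status, case/control characteristics.

The mortality table breaks all-cause and suicide mortality down by disclosed
LGBT status (All / Unknown / Yes / No) with rates at the conventional printed
precisions: all-cause mortality as an integer percent, suicide mortality to
two decimals, and suicide's share of all-cause deaths to one.  The
characteristics table compares cases and matched controls per variable with a
chi-square test (no continuity correction) for categoricals and a two-sample
t-test for age.  Display rounding is half-up; full-precision values are kept
alongside.
"""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd
from scipy import stats

from ehrisk.cohort import DEFAULT_SUICIDE_CODES, is_suicide_cause
from ehrisk.encoding import age_at

__all__ = ["round_half_up", "mortality_rates_from_counts", "mortality_table",
           "characteristics_table", "render_markdown"]

STATUS_ORDER = ["All", "Unknown", "Yes", "No"]


def round_half_up(value: float, ndigits: int = 0) -> float:
    """Decimal round-half-up at ``ndigits`` (display convention)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


def mortality_rates_from_counts(total: int, all_cause_deaths: int,
                                suicide_deaths: int) -> dict[str, float]:
    """The three printed rate columns recomputed from one row of counts.

    Returns all-cause mortality % (integer precision), suicide mortality %
    (two decimals) and suicide share of all-cause deaths % (one decimal),
    plus the unrounded values.  A row with zero deaths reports a zero share
    with ``zero_deaths=True``.
    """
    all_rate = 100.0 * all_cause_deaths / total if total else 0.0
    sui_rate = 100.0 * suicide_deaths / total if total else 0.0
    share = 100.0 * suicide_deaths / all_cause_deaths if all_cause_deaths else 0.0
    return {
        "all_cause_rate_pct": round_half_up(all_rate, 0),
        "suicide_rate_pct": round_half_up(sui_rate, 2),
        "suicide_share_pct": round_half_up(share, 1),
        "all_cause_rate_raw": all_rate,
        "suicide_rate_raw": sui_rate,
        "suicide_share_raw": share,
        "zero_deaths": all_cause_deaths == 0,
    }


def mortality_table(patients: pd.DataFrame, status_column: str = "lgbt_status",
                    suicide_codes=DEFAULT_SUICIDE_CODES) -> pd.DataFrame:
    """Mortality-rate breakdown by disclosed status.

    One row per group (All, Unknown, Yes, No) with total patients, all-cause
    deaths, suicide deaths and the three rate columns; invariant to patient
    row order, and every printed rate equals its ratio of the row's own
    counts after rounding.
    """
    dead = patients["death_date"].notna()
    suicide = dead & patients["underlying_cause"].map(
        lambda c: is_suicide_cause(c, suicide_codes))
    rows = []
    for group in STATUS_ORDER:
        sel = np.ones(len(patients), dtype=bool) if group == "All" \
            else (patients[status_column] == group).to_numpy()
        total = int(sel.sum())
        deaths = int(dead[sel].sum())
        suicides = int(suicide[sel].sum())
        rates = mortality_rates_from_counts(total, deaths, suicides)
        rows.append({"group": group, "total_patients": total,
                     "all_cause_deaths": deaths, "suicide_deaths": suicides, **rates})
    return pd.DataFrame(rows)


CATEGORICAL_VARIABLES = ["sex", "race_ethnicity", "marital_status", "religion", "lgbt_status"]


def characteristics_table(pairs: pd.DataFrame, patients: pd.DataFrame,
                          variables: list[str] | None = None) -> pd.DataFrame:
    """Case/control characteristics with group-comparison statistics.

    Age appears as mean (sd) with a two-sample t-test; each categorical
    appears as per-level counts and integer percentages with one omnibus
    chi-square p-value (no continuity correction).
    """
    if pairs.empty:
        raise ValueError("characteristics_table requires at least one matched pair")
    variables = variables or [v for v in CATEGORICAL_VARIABLES if v in patients.columns]
    by_id = patients.set_index("id")
    cases = by_id.loc[pairs["case_id"]]
    controls = by_id.loc[pairs["control_id"]]
    case_age = np.array([age_at(b, d) for b, d in
                         zip(cases["birth_date"], pairs["case_index_date"])])
    ctrl_age = np.array([age_at(b, d) for b, d in
                         zip(controls["birth_date"], pairs["control_index_date"])])
    tstat, pval = stats.ttest_ind(case_age, ctrl_age, equal_var=False)
    rows = [{
        "variable": "age", "level": "mean (sd)",
        "case_value": f"{round_half_up(case_age.mean(), 1)} ({round_half_up(case_age.std(ddof=1), 1)})",
        "control_value": f"{round_half_up(ctrl_age.mean(), 1)} ({round_half_up(ctrl_age.std(ddof=1), 1)})",
        "case_n": len(case_age), "control_n": len(ctrl_age),
        "case_pct": np.nan, "control_pct": np.nan,
        "statistic": float(tstat), "p_value": float(pval),
        "case_mean": float(case_age.mean()), "control_mean": float(ctrl_age.mean()),
    }]
    for var in variables:
        levels = sorted(set(cases[var]) | set(controls[var]))
        case_counts = cases[var].value_counts()
        ctrl_counts = controls[var].value_counts()
        table = np.array([[case_counts.get(lv, 0) for lv in levels],
                          [ctrl_counts.get(lv, 0) for lv in levels]])
        keep = table.sum(axis=0) > 0
        if keep.sum() > 1:
            chi2, pval, _, _ = stats.chi2_contingency(table[:, keep], correction=False)
        else:
            chi2, pval = 0.0, 1.0
        for lv in levels:
            cn, kn = int(case_counts.get(lv, 0)), int(ctrl_counts.get(lv, 0))
            rows.append({
                "variable": var, "level": lv,
                "case_value": f"{cn} ({round_half_up(100 * cn / len(cases), 0):.0f})",
                "control_value": f"{kn} ({round_half_up(100 * kn / len(controls), 0):.0f})",
                "case_n": cn, "control_n": kn,
                "case_pct": round_half_up(100 * cn / len(cases), 0),
                "control_pct": round_half_up(100 * kn / len(controls), 0),
                "statistic": float(chi2), "p_value": float(pval),
                "case_mean": np.nan, "control_mean": np.nan,
            })
    return pd.DataFrame(rows)


def render_markdown(table: pd.DataFrame, title: str) -> str:
    """Simple Markdown rendering of a report table."""
    cols = [c for c in table.columns if not c.endswith("_raw") and c not in
            ("case_mean", "control_mean", "zero_deaths")]
    lines = [f"## {title}", "", "| " + " | ".join(cols) + " |",
             "|" + "|".join("---" for _ in cols) + "|"]
    for _, row in table.iterrows():
        lines.append("| " + " | ".join(str(row[c]) for c in cols) + " |")
    return "\n".join(lines) + "\n"
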