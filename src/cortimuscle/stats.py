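"""Group-level statistical battery: Shapiro-Wilk normality screening and
independent / paired two-tailed t-tests per outcome at alpha = 0.05.

No multiple-comparison correction is applied by default (each outcome is
tested at its own nominal level); a Benjamini-Hochberg FDR adjustment is
available behind a flag for sensitivity analysis.  Non-normal outcomes are
still t-tested, with the normality flag carried in the output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as ss
from statsmodels.stats.multitest import multipletests

ALPHA = 0.05


@dataclass
class ComparisonResult:
    outcome: str
    design: str  # 'independent' | 'paired'
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    n_a: int
    n_b: int
    t: float
    p: float
    normality_p_a: float
    normality_p_b: float
    significant: bool
    p_adjusted: float | None = None


def normality_check(sample: np.ndarray) -> float:
    """Shapiro-Wilk p-value; p < 0.05 flags departure from normality."""
    sample = np.asarray(sample, dtype=float)
    if sample.size < 3:
        raise ValueError(f"Shapiro-Wilk needs n >= 3, got {sample.size}")
    if sample.size > 5000:
        raise ValueError("Shapiro-Wilk is unreliable above n = 5000")
    if np.ptp(sample) == 0:
        # degenerate constant sample: normality undefined
        return float("nan")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(ss.shapiro(sample).pvalue)


def _safe_normality(sample: np.ndarray) -> float:
    try:
        return normality_check(sample)
    except ValueError:
        return float("nan")


def compare_groups(a: np.ndarray, b: np.ndarray, design: str,
                   outcome: str = "", alpha: float = ALPHA) -> ComparisonResult:
    """Two-tailed t-test of the stated design with descriptive statistics."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if design == "paired":
        if a.size != b.size:
            raise ValueError(f"paired design needs equal lengths, got {a.size} and {b.size}")
        if a.size < 2:
            raise ValueError("paired t-test needs n >= 2")
        if np.ptp(a - b) == 0:
            # zero-variance differences: identical samples -> no effect
            t, p = 0.0, 1.0
        else:
            t, p = ss.ttest_rel(a, b)
    elif design == "independent":
        if min(a.size, b.size) < 2:
            raise ValueError("independent t-test needs n >= 2 per group")
        t, p = ss.ttest_ind(a, b)
    else:
        raise ValueError(f"unknown design {design!r}")
    return ComparisonResult(
        outcome=outcome, design=design,
        mean_a=float(a.mean()), sd_a=float(a.std(ddof=1)) if a.size > 1 else float("nan"),
        mean_b=float(b.mean()), sd_b=float(b.std(ddof=1)) if b.size > 1 else float("nan"),
        n_a=int(a.size), n_b=int(b.size),
        t=float(t), p=float(p),
        normality_p_a=_safe_normality(a), normality_p_b=_safe_normality(b),
        significant=bool(p < alpha),
    )


def outcome_battery(table: pd.DataFrame, design: str,
                    group_col: str = "group", outcome_col: str = "outcome",
                    value_col: str = "value", subject_col: str = "subject",
                    alpha: float = ALPHA, fdr: bool = False) -> pd.DataFrame:
    """One two-tailed t-test per outcome id over a tidy table.

    The tidy table has one row per (subject, group/condition, outcome).
    Paired designs match observations by subject.  Outcomes with fewer than
    two observations in either cell are skipped and flagged.  With
    ``fdr=True`` Benjamini-Hochberg adjusted p-values are appended (a
    deviation from uncorrected per-outcome testing, hence warned).
    """
    levels = sorted(table[group_col].unique())
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 levels in {group_col!r}, got {levels}")
    la, lb = levels
    rows, skipped = [], []
    for outcome, sub in table.groupby(outcome_col, sort=True):
        if design == "paired":
            wide = sub.pivot(index=subject_col, columns=group_col, values=value_col).dropna()
            a, b = wide[la].to_numpy(), wide[lb].to_numpy()
        else:
            a = sub.loc[sub[group_col] == la, value_col].to_numpy()
            b = sub.loc[sub[group_col] == lb, value_col].to_numpy()
        if min(len(a), len(b)) < 2:
            skipped.append(outcome)
            continue
        rows.append(compare_groups(a, b, design, outcome=str(outcome), alpha=alpha))
    out = pd.DataFrame([vars(r) for r in rows]).drop(columns=["p_adjusted"],
                                                     errors="ignore")
    if skipped:
        warnings.warn(f"outcomes skipped for insufficient observations: {skipped}",
                      stacklevel=2)
        out.attrs["skipped"] = skipped
    if fdr and len(out):
        warnings.warn("FDR adjustment applied; the default reporting is uncorrected",
                      stacklevel=2)
        out["p_adjusted"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
        out["significant_adjusted"] = out["p_adjusted"] < alpha
    return out


def two_sample_t_power(delta_sd: float, n1: int, n2: int, alpha: float = ALPHA) -> float:
    """Closed-form power of the two-sided two-sample t-test for a mean shift
    of ``delta_sd`` standard deviations (noncentral-t formulation)."""
    df = n1 + n2 - 2
    ncp = delta_sd / np.sqrt(1.0 / n1 + 1.0 / n2)
    tcrit = ss.t.ppf(1.0 - alpha / 2.0, df)
    return float(ss.nct.sf(tcrit, df, ncp) + ss.nct.cdf(-tcrit, df, ncp))
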