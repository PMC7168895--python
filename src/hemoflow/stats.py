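"""Two-group biostatistics for the small-vs-large aneurysm comparison.

Groups are summarized as mean +/- sample SD.  Each variable is compared
with a normality-gated two-sample test: Shapiro-Wilk on each group at
alpha = 0.05; if both groups look normal an independent-sample
(pooled-variance Student) t-test is used, otherwise the two-sided
Mann-Whitney rank-sum test (exact enumeration for small tie-free samples,
normal approximation with tie correction otherwise).  Significance is
declared at p < alpha (default 0.05), per variable, with no
multiple-testing correction.

Derived effect descriptors follow the reporting conventions of the
clinical literature: percent increases are truncated to one decimal and
fold changes rounded half-up.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass(frozen=True)
class GroupSummary:
    mean: float
    sd: float
    n: int
    degenerate: bool = False  # n == 1: SD reported as 0 with this flag set


def group_summary(values) -> GroupSummary:
    """Mean and sample SD (n-1 denominator) of one group."""
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("empty group")
    if x.size == 1:
        return GroupSummary(mean=float(x[0]), sd=0.0, n=1, degenerate=True)
    return GroupSummary(mean=float(x.mean()), sd=float(x.std(ddof=1)), n=int(x.size))


@dataclass(frozen=True)
class GroupComparison:
    variable: str
    small_mean: float
    small_sd: float
    n_small: int
    large_mean: float
    large_sd: float
    n_large: int
    test_used: str  # "t_test" | "mann_whitney" | "degenerate"
    p_value: float
    significant: bool
    alpha: float = 0.05


def compare_groups(
    small, large, alpha: float = 0.05, variable: str = "", welch: bool = False
) -> GroupComparison:
    """Normality-gated two-sample comparison of the small and large groups.

    Both groups need n >= 3 for the Shapiro-Wilk gate.  If the pooled data
    are all identical the comparison is degenerate and p is reported as 1.
    ``welch=True`` swaps the pooled-variance t-test for Welch's.
    """
    s = np.asarray(small, dtype=float)
    l = np.asarray(large, dtype=float)
    if s.size < 3 or l.size < 3:
        raise ValueError("each group needs at least 3 observations for the normality gate")
    gs, gl = group_summary(s), group_summary(l)

    pooled = np.concatenate([s, l])
    if np.ptp(pooled) == 0:
        return GroupComparison(
            variable=variable,
            small_mean=gs.mean, small_sd=gs.sd, n_small=gs.n,
            large_mean=gl.mean, large_sd=gl.sd, n_large=gl.n,
            test_used="degenerate", p_value=1.0, significant=False, alpha=alpha,
        )

    def _normal(x):
        if np.ptp(x) == 0:
            return False  # constant group: Shapiro undefined, clearly non-normal gate
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return sps.shapiro(x).pvalue >= 0.05

    if _normal(s) and _normal(l):
        res = sps.ttest_ind(s, l, equal_var=not welch)
        test, p = "t_test", float(res.pvalue)
    else:
        p = mann_whitney_p(s, l)
        test = "mann_whitney"
    return GroupComparison(
        variable=variable,
        small_mean=gs.mean, small_sd=gs.sd, n_small=gs.n,
        large_mean=gl.mean, large_sd=gl.sd, n_large=gl.n,
        test_used=test, p_value=p, significant=bool(p < alpha), alpha=alpha,
    )


def mann_whitney_p(x, y) -> float:
    """Two-sided Mann-Whitney p: exact enumeration for tie-free samples of
    at most 20 per group, else the normal approximation with tie
    correction and continuity correction."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    method = "exact" if (not ties and max(x.size, y.size) <= 20) else "asymptotic"
    return float(sps.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue)


def percent_increase(base: float, other: float) -> float:
    """100 (other - base) / base, truncated to one decimal.

    Truncation (not rounding) matches how percent increases are quoted from
    rounded group means: (3.8, 6.2) -> 63.1."""
    if base <= 0:
        raise ValueError("base must be positive")
    val = 100.0 * (other - base) / base
    return math.trunc(round(val * 10.0, 6)) / 10.0


def fold_change(numerator: float, denominator: float, decimals: int = 1) -> float:
    """numerator / denominator rounded half-up to ``decimals``."""
    if numerator <= 0 or denominator <= 0:
        raise ValueError("fold change needs positive inputs")
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(numerator / denominator)).quantize(q, rounding=ROUND_HALF_UP))


def format_p(p: float) -> str:
    """Three-decimal p-value string with '<0.001' flooring."""
    if not (0 <= p <= 1):
        raise ValueError("p must lie in [0, 1]")
    return "<0.001" if p < 0.001 else f"{p:.3f}"


# ---------------------------------------------------------------------------
# tables

_TABLE_VARS = {
    "table1": [
        ("height_mm", "Height (mm)"),
        ("width_mm", "Width (mm)"),
        ("ostium_diameter_mm", "Ostium diameter (mm)"),
        ("ostium_area_mm2", "Cross-sectional area of ostium (mm^2)"),
        ("surface_area_mm2", "Surface area of aneurysm (mm^2)"),
    ],
    "table2": [
        ("avg_shear_rate_ps_per_s", "Average shear rate at PS (1/s)"),
        ("avg_shear_rate_ed_per_s", "Average shear rate at ED (1/s)"),
    ],
    "table3": [
        ("avg_viscosity_ps_cp", "Average viscosity at PS (cP)"),
        ("avg_viscosity_ed_cp", "Average viscosity at ED (cP)"),
    ],
    "table4": [
        ("wss_min_pa", "Minimal wall shear stress (Pa)"),
        ("wss_tavg_pa", "Time-averaged wall shear stress (Pa)"),
        ("wss_max_pa", "Maximal wall shear stress (Pa)"),
    ],
}


def make_group_tables(results: pd.DataFrame, alpha: float = 0.05) -> dict[str, pd.DataFrame]:
    """Build the four group-comparison tables from per-patient results.

    ``results`` must carry one row per patient with a ``size_class`` column
    ('small'/'large') and the morphometric and hemodynamic columns named as
    in :data:`_TABLE_VARS`.  Returns a dict of tidy DataFrames (variable,
    group means +/- SD, test, p, significance star).  If one group is
    empty, comparison columns are left missing with a warning.
    """
    if "size_class" not in results.columns:
        raise ValueError("results need a size_class column")
    needed = [c for vars_ in _TABLE_VARS.values() for c, _ in vars_]
    missing_cols = [c for c in needed if c not in results.columns]
    if missing_cols:
        raise ValueError(f"results missing columns: {missing_cols}")
    for col in needed:
        bad = results[results[col].isna()]
        if len(bad):
            ids = bad.get("patient_id", bad.index).tolist()
            raise ValueError(f"variable {col} missing for patients {ids}")

    small = results[results["size_class"] == "small"]
    large = results[results["size_class"] == "large"]
    one_group = len(small) == 0 or len(large) == 0
    if one_group:
        warnings.warn("only one size group present; comparison columns left empty", UserWarning, stacklevel=2)
    elif len(small) < 3 or len(large) < 3:
        warnings.warn("fewer than 3 patients in a group; comparison tests skipped", UserWarning, stacklevel=2)

    tables = {}
    for name, vars_ in _TABLE_VARS.items():
        rows = []
        for col, label in vars_:
            row = {"variable": label}
            for grp, df in (("small", small), ("large", large)):
                if len(df):
                    gsum = group_summary(df[col].to_numpy())
                    row[f"{grp}_mean"] = gsum.mean
                    row[f"{grp}_sd"] = gsum.sd
                    row[f"{grp}_n"] = gsum.n
                else:
                    row[f"{grp}_mean"] = row[f"{grp}_sd"] = np.nan
                    row[f"{grp}_n"] = 0
            if not one_group and len(small) >= 3 and len(large) >= 3:
                cmpres = compare_groups(
                    small[col].to_numpy(), large[col].to_numpy(), alpha=alpha, variable=label
                )
                row["test"] = cmpres.test_used
                row["p_value"] = cmpres.p_value
                row["p"] = format_p(cmpres.p_value)
                row["significant"] = "*" if cmpres.significant else ""
            else:
                row["test"] = ""
                row["p_value"] = np.nan
                row["p"] = ""
                row["significant"] = ""
            rows.append(row)
        tables[name] = pd.DataFrame(rows)
    return tables
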