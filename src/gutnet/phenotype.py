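"""Clinical-trait statistics for microbiota community types.

Covers the cardiometabolic side of the pipeline: NHLBI-style metabolic
syndrome trait flags (medication use substitutes for measured values),
Friedewald LDL, age/sex-adjusted correlations, the 2-df class-variable
association test of community type against each trait with adjusted
(least-squares) means, Wilcoxon rank-sum diversity comparisons, occupation
cross-tabulations, and subgroup abundance comparisons with
Benjamini-Hochberg correction.

Metabolic syndrome trait criteria (waist circumference deliberately
excluded):

* triglycerides: TG > 150 mg/dl, or on TG-lowering medication;
* HDL: <= 50 mg/dl (women), < 40 mg/dl (men), or on HDL-raising medication;
* blood pressure: SBP > 130 or DBP > 85 mmHg, or on anti-hypertensives;
* glucose: fasting glucose >= 100 mg/dl, or on anti-diabetic medication.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .abundance import CountTable, UNASSIGNED, relative_abundance
from .exceptions import GutnetError

__all__ = [
    "OCCUPATION_CLASSES",
    "mets_flags",
    "friedewald_ldl",
    "adjusted_correlation",
    "group_association",
    "GroupAssociationResult",
    "wilcoxon_rank_sum",
    "occupation_crosstab",
    "subgroup_abundance_compare",
]

OCCUPATION_CLASSES = (
    "farmer",
    "tradesman",
    "farmer's wife",
    "teacher/shopkeeper",
    "unknown/retired",
)

_MED_COLS = {
    "tg": "med_tg_lowering",
    "hdl": "med_hdl_raising",
    "bp": "med_antihypertensive",
    "glucose": "med_antidiabetic",
}


def _flag_or_na(value_flag, med_flag) -> object:
    """Combine a value-based criterion (may be NA) with a medication flag."""
    if med_flag:
        return True
    return value_flag  # may be pd.NA when the measurement is missing


def mets_flags(panel: pd.DataFrame, hdl_male_rule: str = "strict-less") -> pd.DataFrame:
    """Per-subject metabolic syndrome trait flags.

    ``panel`` needs columns sex ('M'/'F'), tg, hdl, sbp, dbp, glucose and the
    four medication flag columns (missing medication columns are treated as
    all-False).  Missing measurements with no medication flag leave that
    criterion undetermined (pd.NA) and excluded from the count, with a
    warning.  ``hdl_male_rule`` selects '<40' (default) or '<=40' for men;
    both conventions appear in the field.
    """
    if hdl_male_rule not in ("strict-less", "less-equal"):
        raise ValueError("hdl_male_rule must be 'strict-less' or 'less-equal'")
    if "sex" not in panel.columns:
        raise GutnetError("panel must have a 'sex' column")
    meds = {}
    for key, col in _MED_COLS.items():
        if col in panel.columns:
            meds[key] = panel[col].fillna(False).astype(bool)
        else:
            meds[key] = pd.Series(False, index=panel.index)

    def crit(values: pd.Series, rule) -> pd.Series:
        out = pd.Series(pd.NA, index=panel.index, dtype="boolean")
        ok = values.notna()
        out[ok] = rule(values[ok])
        return out

    tg = crit(pd.to_numeric(panel.get("tg"), errors="coerce"), lambda v: v > 150)
    glu = crit(pd.to_numeric(panel.get("glucose"), errors="coerce"), lambda v: v >= 100)
    sbp = pd.to_numeric(panel.get("sbp"), errors="coerce")
    dbp = pd.to_numeric(panel.get("dbp"), errors="coerce")
    bp = pd.Series(pd.NA, index=panel.index, dtype="boolean")
    any_bp = sbp.notna() | dbp.notna()
    bp[any_bp] = (sbp[any_bp] > 130) | (dbp[any_bp] > 85)
    hdl = pd.to_numeric(panel.get("hdl"), errors="coerce")
    female = panel["sex"].astype(str).str.upper().isin(["F", "FEMALE"])
    hdl_flag = pd.Series(pd.NA, index=panel.index, dtype="boolean")
    ok = hdl.notna()
    male_cut = (hdl < 40) if hdl_male_rule == "strict-less" else (hdl <= 40)
    hdl_flag[ok] = np.where(female[ok], hdl[ok] <= 50, male_cut[ok])

    flags = pd.DataFrame(index=panel.index)
    for name, value_flag, med in [
        ("tg_flag", tg, meds["tg"]),
        ("hdl_flag", hdl_flag, meds["hdl"]),
        ("bp_flag", bp, meds["bp"]),
        ("glucose_flag", glu, meds["glucose"]),
    ]:
        combined = value_flag.copy()
        combined[med] = True  # medication substitutes for the measurement
        flags[name] = combined.astype("boolean")
    undetermined = flags.isna().any(axis=1)
    if undetermined.any():
        warnings.warn(
            f"{int(undetermined.sum())} subject(s) with undetermined criteria "
            "(missing value, no medication flag); excluded from counts",
            stacklevel=2,
        )
    flags["n_traits"] = flags[
        ["tg_flag", "hdl_flag", "bp_flag", "glucose_flag"]
    ].sum(axis=1, skipna=True).astype(int)
    flags["any_trait"] = flags["n_traits"] >= 1
    return flags


def friedewald_ldl(tc, hdl, tg):
    """Friedewald LDL = TC - HDL - TG/5 (mg/dl); undefined (NaN) for TG >= 400."""
    tc = np.asarray(tc, dtype=float)
    hdl = np.asarray(hdl, dtype=float)
    tg = np.asarray(tg, dtype=float)
    invalid = tg >= 400
    if np.any(invalid):
        warnings.warn(
            "Friedewald formula undefined for TG >= 400 mg/dl; returning NaN",
            stacklevel=2,
        )
    ldl = tc - hdl - tg / 5.0
    ldl = np.where(invalid, np.nan, ldl)
    return float(ldl) if ldl.ndim == 0 else ldl


def _residualize(y: np.ndarray, design: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    return y - design @ beta


def adjusted_correlation(
    x: Sequence[float],
    y: Sequence[float],
    covariates: pd.DataFrame,
    method: str = "pearson",
) -> tuple[float, float]:
    """Correlation of x and y after residualizing both on covariates.

    Both variables are regressed on [1, covariates] by least squares; the
    correlation of the residuals is tested on n - 2 - k degrees of freedom
    (k = number of covariates).  ``method`` is 'pearson' (default) or
    'spearman' (ranks of residuals).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    cov = covariates.to_numpy(dtype=float)
    n, k = cov.shape
    if len(x) != n or len(y) != n:
        raise GutnetError("x, y and covariates must be aligned")
    if n < k + 3:
        raise GutnetError("too few observations for adjustment")
    design = np.column_stack([np.ones(n), cov])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise GutnetError("collinear covariates")
    rx = _residualize(x, design)
    ry = _residualize(y, design)
    if method == "spearman":
        rx = stats.rankdata(rx)
        ry = stats.rankdata(ry)
    elif method != "pearson":
        raise ValueError(f"unknown method {method!r}")
    r = float(np.corrcoef(rx, ry)[0, 1])
    df = n - 2 - k
    if abs(r) >= 1.0:
        return float(np.sign(r)), 0.0
    t = r * np.sqrt(df / (1 - r**2))
    p = float(2 * stats.t.sf(abs(t), df))
    return r, p


@dataclass
class GroupAssociationResult:
    """2-df community-type association for one trait."""

    trait: str
    kind: str  # "linear" or "logistic"
    p_value: float  # 2-df F (linear) or LR (logistic) p
    adjusted_means: pd.DataFrame  # index group; columns mean, se (linear only)
    contrasts: pd.DataFrame | None  # pairwise contrasts when p < gate
    n: int


def group_association(
    trait: pd.Series,
    groups: pd.Series,
    covariates: pd.DataFrame | None = None,
    binary: bool = False,
    contrast_gate: float = 0.05,
) -> GroupAssociationResult:
    """Association of a trait with a 3-level community-type class variable.

    Linear traits: least squares of trait ~ intercept + covariates + group
    indicators; the group effect is the 2-df F-test of the full model against
    the covariates-only model, and per-group adjusted (least-squares) means
    are evaluated at the covariate means.  Binary traits use logistic
    regression with a 2-df likelihood-ratio test.  Pairwise contrasts
    (each group vs the other two pooled) are computed only when the overall
    test passes ``contrast_gate``.
    """
    import statsmodels.api as sm

    data = pd.DataFrame({"trait": pd.to_numeric(trait, errors="coerce")})
    data["group"] = groups.reindex(trait.index)
    if covariates is not None:
        cov = covariates.reindex(trait.index).astype(float)
        data = data.join(cov)
        cov_cols = list(cov.columns)
    else:
        cov_cols = []
    data = data.dropna()
    levels = sorted(data["group"].unique())
    if len(levels) < 3:
        raise GutnetError("need all 3 community-type levels represented")
    counts = data["group"].value_counts()
    small = counts[counts < 2]
    if len(small) > 0:
        raise GutnetError(f"group(s) with <2 members: {list(small.index)}")
    n = len(data)
    y = data["trait"].to_numpy(dtype=float)
    x_cov = np.column_stack(
        [np.ones(n)] + [data[c].to_numpy(dtype=float) for c in cov_cols]
    )
    # group indicators for levels 2..k (level 1 is reference)
    indicators = np.column_stack(
        [(data["group"] == lev).to_numpy(dtype=float) for lev in levels[1:]]
    )
    x_full = np.column_stack([x_cov, indicators])

    if binary:
        uniq = set(np.unique(y))
        if not uniq <= {0.0, 1.0}:
            raise GutnetError("binary trait must be coded 0/1")
        full = sm.Logit(y, x_full).fit(disp=0)
        red = sm.Logit(y, x_cov).fit(disp=0)
        lr = 2 * (full.llf - red.llf)
        p_overall = float(stats.chi2.sf(lr, len(levels) - 1))
        # adjusted prevalence at covariate means
        rows = {}
        cov_mean = x_cov.mean(axis=0)
        for i, lev in enumerate(levels):
            xrow = np.concatenate(
                [cov_mean, [1.0 if j == i - 1 else 0.0 for j in range(len(levels) - 1)]]
            )
            eta = float(xrow @ full.params)
            rows[lev] = {"mean": 1 / (1 + np.exp(-eta)), "se": np.nan}
        adj = pd.DataFrame.from_dict(rows, orient="index")
        kind = "logistic"
        fit_for_contrast = None
    else:
        full = sm.OLS(y, x_full).fit()
        red = sm.OLS(y, x_cov).fit()
        df_num = len(levels) - 1
        df_den = n - x_full.shape[1]
        f = ((red.ssr - full.ssr) / df_num) / (full.ssr / df_den)
        p_overall = float(stats.f.sf(f, df_num, df_den))
        cov_mean = x_cov.mean(axis=0)
        rows = {}
        cov_params = full.cov_params()
        for i, lev in enumerate(levels):
            xrow = np.concatenate(
                [cov_mean, [1.0 if j == i - 1 else 0.0 for j in range(len(levels) - 1)]]
            )
            mean = float(xrow @ full.params)
            se = float(np.sqrt(xrow @ cov_params @ xrow))
            rows[lev] = {"mean": mean, "se": se}
        adj = pd.DataFrame.from_dict(rows, orient="index")
        kind = "linear"
        fit_for_contrast = full

    contrasts = None
    if p_overall < contrast_gate:
        crows = []
        for lev in levels:
            mask = (data["group"] == lev).to_numpy(dtype=float)
            sub = data.copy()
            sub["_ind"] = mask
            x_c = np.column_stack([x_cov, mask])
            if binary:
                fit_c = sm.Logit(y, x_c).fit(disp=0)
                red_c = sm.Logit(y, x_cov).fit(disp=0)
                lr_c = 2 * (fit_c.llf - red_c.llf)
                p_c = float(stats.chi2.sf(lr_c, 1))
            else:
                fit_c = sm.OLS(y, x_c).fit()
                p_c = float(fit_c.pvalues[-1])
            crows.append({"contrast": f"{lev} vs rest", "p": p_c})
        contrasts = pd.DataFrame(crows)
    adj.index.name = "group"
    return GroupAssociationResult(
        trait=str(trait.name) if trait.name is not None else "trait",
        kind=kind,
        p_value=p_overall,
        adjusted_means=adj,
        contrasts=contrasts,
        n=n,
    )


def wilcoxon_rank_sum(
    x: Sequence[float], y: Sequence[float]
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact enumeration when m + n <= 20 and there are no ties, otherwise the
    tie-corrected normal approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise GutnetError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    no_ties = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (len(x) + len(y) <= 20 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def occupation_crosstab(
    assignments: pd.Series,
    metadata: pd.DataFrame,
    stratify_by: str = "sex",
) -> dict[str, pd.DataFrame]:
    """Occupation x community-type counts with within-type column percentages.

    Returns one frame per stratum (e.g. per sex); cells are formatted
    "count (percent)" alongside numeric columns.  Unknown occupations fall
    into 'unknown/retired'.
    """
    meta = metadata.copy()
    occ = meta.get("occupation")
    if occ is None:
        raise GutnetError("metadata must have an 'occupation' column")
    occ = occ.fillna("unknown/retired").replace("", "unknown/retired")
    meta["occupation"] = occ.where(occ.isin(OCCUPATION_CLASSES), "unknown/retired")
    meta["group"] = assignments.reindex(meta.index)
    out = {}
    strata = meta[stratify_by].dropna().unique() if stratify_by else ["all"]
    for stratum in sorted(map(str, strata)):
        sub = meta if stratify_by is None else meta[meta[stratify_by].astype(str) == stratum]
        counts = pd.crosstab(sub["occupation"], sub["group"])
        counts = counts.reindex(
            index=[o for o in OCCUPATION_CLASSES if o in counts.index]
        )
        pct = 100 * counts / counts.sum(axis=0)
        merged = pd.DataFrame(index=counts.index)
        for col in counts.columns:
            merged[f"network_{col}_n"] = counts[col]
            merged[f"network_{col}_pct"] = pct[col].round(1)
        out[stratum] = merged
    return out


def subgroup_abundance_compare(
    table: CountTable,
    mask: pd.Series | Sequence[bool],
    min_prevalence: float = 0.10,
) -> pd.DataFrame:
    """Per-taxon subset-vs-complement comparison of relative abundances.

    Wilcoxon rank-sum per taxon with Benjamini-Hochberg q-values; taxa below
    the prevalence floor are excluded.  Returns median difference
    (subset - complement), p and q, sorted by q ascending.
    """
    from statsmodels.stats.multitest import multipletests

    mask = pd.Series(np.asarray(mask, dtype=bool), index=table.samples)
    if mask.sum() == 0:
        raise GutnetError("empty subset")
    if (~mask).sum() == 0:
        raise GutnetError("empty complement")
    rel = relative_abundance(table)
    prev = (table.data >= 1).sum(axis=1) / table.n_samples
    keep = [t for t in rel.index if prev[t] >= min_prevalence and t != UNASSIGNED]
    rows = []
    for taxon in keep:
        a = rel.loc[taxon, mask].to_numpy()
        b = rel.loc[taxon, ~mask].to_numpy()
        if np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
            continue
        _, p = wilcoxon_rank_sum(a, b)
        rows.append(
            {
                "taxon": taxon,
                "median_diff": float(np.median(a) - np.median(b)),
                "p": p,
            }
        )
    frame = pd.DataFrame(rows)
    if len(frame) > 0:
        frame["q"] = multipletests(frame["p"], method="fdr_bh")[1]
        frame = frame.sort_values(["q", "p", "taxon"]).reset_index(drop=True)
    return frame
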