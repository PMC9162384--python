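"""Region-wise group comparison, FDR control, clinical correlation and
outlier screening.

The group contrast is a two-sided pooled-variance (Student) two-sample t-test
per region, with the sign convention that positive t means patients > controls.
Multiplicity is controlled per metric across regions with the
Benjamini-Hochberg step-up procedure; a feature is declared significant when
its adjusted p is strictly below the chosen alpha (0.001 for discovery, 0.05
for the classifier's feature gate).

Clinical coupling is assessed with Pearson correlation between significant
features and the UMSARS-total score of patients, selected at raw p < 0.001.
Before correlating, subjects can be screened for outliers with a normal Q-Q
plot; because a visual call is not reproducible, an automatic robust-z rule
(|value - median| / (1.4826 * MAD) > k, default k = 3.5) backs the plot, and a
manual exclusion list overrides it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "RegionStatsResult",
    "QQScreenResult",
    "pooled_ttest",
    "two_sample_t",
    "bh_fdr",
    "select_significant",
    "demographic_tests",
    "clinical_correlation",
    "qq_outlier_screen",
]


@dataclass
class RegionStatsResult:
    """Per-region t statistics with BH-adjusted p-values for one metric."""

    metric: str
    region_labels: list[str]
    t: np.ndarray
    p: np.ndarray
    p_fdr: np.ndarray
    n_patients: int
    n_controls: int
    tested: np.ndarray = field(default=None)  # False where a region was excluded

    def significant(self, alpha: float) -> np.ndarray:
        """Indices of regions with adjusted p strictly below ``alpha``."""
        with np.errstate(invalid="ignore"):
            flags = self.p_fdr < alpha
        flags = np.where(np.isnan(self.p_fdr), False, flags)
        return np.flatnonzero(flags)

    def to_frame(self, alpha: float = 0.001) -> pd.DataFrame:
        sig = np.zeros(len(self.region_labels), bool)
        sig[self.significant(alpha)] = True
        return pd.DataFrame(
            {
                "metric": self.metric,
                "region": self.region_labels,
                "t": self.t,
                "p": self.p,
                "p_fdr": self.p_fdr,
                "significant": sig,
            }
        )


def pooled_ttest(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized two-sided pooled-variance t-test along axis 0 (a minus b).

    Columns where both samples have zero variance give t = 0, p = 1 (with a
    warning) rather than NaN.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    na, nb = a.shape[0], b.shape[0]
    if na < 2 or nb < 2:
        raise ValueError("each group needs at least 2 observations")
    ma, mb = a.mean(axis=0), b.mean(axis=0)
    va, vb = a.var(axis=0, ddof=1), b.var(axis=0, ddof=1)
    df = na + nb - 2
    sp = ((na - 1) * va + (nb - 1) * vb) / df
    denom = np.sqrt(sp * (1.0 / na + 1.0 / nb))
    zero = denom == 0
    if np.any(zero):
        warnings.warn(
            f"{int(np.count_nonzero(zero))} column(s) with zero variance in both "
            "groups; t set to 0, p to 1",
            stacklevel=2,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(zero, 0.0, (ma - mb) / np.where(zero, 1.0, denom))
    p = np.where(zero, 1.0, 2.0 * stats.t.sf(np.abs(t), df))
    return t, p


def two_sample_t(
    table: pd.DataFrame,
    metric: str = "",
    group_col: str = "group",
    patient_label: str = "patient",
    alpha: float = 0.001,
    welch: bool = False,
) -> RegionStatsResult:
    """Region-wise group contrast on a subjects x regions feature table.

    Regions with fewer than 2 non-missing values in either group are excluded
    (NaN in the output) with a warning, never silently zeroed.
    """
    region_cols = [c for c in table.columns if c not in ("subject_id", group_col)]
    values = table[region_cols].to_numpy(float)
    is_patient = (table[group_col] == patient_label).to_numpy()
    a, b = values[is_patient], values[~is_patient]
    R = len(region_cols)
    t_out = np.full(R, np.nan)
    p_out = np.full(R, np.nan)
    ok_a = (~np.isnan(a)).sum(axis=0) >= 2
    ok_b = (~np.isnan(b)).sum(axis=0) >= 2
    tested = ok_a & ok_b
    if not tested.all():
        dropped = [region_cols[i] for i in np.flatnonzero(~tested)]
        warnings.warn(
            f"excluding region(s) with <2 values in a group: {dropped}", stacklevel=2
        )
    if tested.any():
        if np.isnan(values).any():
            # per-region listwise deletion
            for i in np.flatnonzero(tested):
                ai = a[:, i][~np.isnan(a[:, i])]
                bi = b[:, i][~np.isnan(b[:, i])]
                if welch:
                    res = stats.ttest_ind(ai, bi, equal_var=False)
                    t_out[i], p_out[i] = res.statistic, res.pvalue
                else:
                    ti, pi = pooled_ttest(ai[:, None], bi[:, None])
                    t_out[i], p_out[i] = ti[0], pi[0]
        else:
            if welch:
                res = stats.ttest_ind(a[:, tested], b[:, tested], equal_var=False)
                t_out[tested], p_out[tested] = res.statistic, res.pvalue
            else:
                t_out[tested], p_out[tested] = pooled_ttest(a[:, tested], b[:, tested])
    p_fdr = np.full(R, np.nan)
    if tested.any():
        p_fdr[tested] = bh_fdr(p_out[tested])
    return RegionStatsResult(
        metric=metric,
        region_labels=region_cols,
        t=t_out,
        p=p_out,
        p_fdr=p_fdr,
        n_patients=int(is_patient.sum()),
        n_controls=int((~is_patient).sum()),
        tested=tested,
    )


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (original order kept)."""
    p = np.asarray(pvals, float)
    if p.ndim != 1:
        raise ValueError("pvals must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any(np.isnan(p)) or np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def select_significant(result: RegionStatsResult, alpha: float = 0.001) -> list[str]:
    """Region labels whose BH-adjusted p is strictly below ``alpha``."""
    return [result.region_labels[i] for i in result.significant(alpha)]


def demographic_tests(
    clinical: pd.DataFrame,
    group_col: str = "group",
    patient_label: str = "patient",
) -> dict[str, float]:
    """Group-matching tests: independent-samples t for age, Pearson chi-square
    (1 df, no continuity correction) for the 2 x 2 group-by-gender table."""
    is_patient = (clinical[group_col] == patient_label).to_numpy()
    if is_patient.all() or not is_patient.any():
        raise ValueError("both groups must be non-empty")
    age_p = clinical.loc[is_patient, "age"].to_numpy(float)
    age_c = clinical.loc[~is_patient, "age"].to_numpy(float)
    if np.array_equal(np.sort(age_p), np.sort(age_c)):
        age_pval = 1.0
    else:
        age_pval = float(stats.ttest_ind(age_p, age_c, equal_var=True).pvalue)

    table = pd.crosstab(clinical[group_col], clinical["gender"]).to_numpy()
    if table.shape != (2, 2):
        raise ValueError("gender table is not 2 x 2")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("a margin of the gender table is zero")
    gender_pval = float(stats.chi2_contingency(table, correction=False)[1])
    return {"age_p": age_pval, "gender_p": gender_pval}


def clinical_correlation(
    tables: dict[str, pd.DataFrame],
    clinical: pd.DataFrame,
    features: list[tuple[str, str]],
    score_col: str = "umsars_total",
    exclude: tuple[str, ...] = (),
    alpha: float = 0.001,
) -> pd.DataFrame:
    """Pearson correlation of each (metric, region) feature against the
    UMSARS-total score of patients, after subject exclusions.

    Returns a tidy frame with r, two-sided p, n used, and a ``selected`` flag
    at raw p strictly below ``alpha``.
    """
    scores = clinical.set_index("subject_id")[score_col]
    rows = []
    for metric, region in features:
        table = tables[metric].set_index("subject_id")
        if region not in table.columns:
            raise KeyError(f"region {region!r} not present in {metric} table")
        feat = table[region]
        paired = pd.concat({"feature": feat, "score": scores}, axis=1).dropna()
        paired = paired[~paired.index.isin(exclude)]
        if len(paired) < 3:
            raise ValueError(
                f"fewer than 3 paired observations for {metric}/{region}"
            )
        x = paired["feature"].to_numpy(float)
        if x.std() == 0:
            raise ValueError(f"feature {metric}/{region} has zero variance")
        r, p = stats.pearsonr(x, paired["score"].to_numpy(float))
        rows.append(
            {
                "metric": metric,
                "region": region,
                "r": float(r),
                "p": float(p),
                "n": len(paired),
                "excluded": ",".join(sorted(exclude)),
                "selected": bool(p < alpha),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class QQScreenResult:
    subject_ids: list[str]
    theoretical: np.ndarray  # normal quantiles, sorted order
    ordered: np.ndarray  # sample values, sorted order
    robust_z: np.ndarray  # aligned with subject_ids
    flagged: list[str]


def qq_outlier_screen(
    values: pd.Series,
    k: float = 3.5,
    manual_exclusions: tuple[str, ...] = (),
) -> QQScreenResult:
    """Normal Q-Q coordinates plus an automatic robust-z outlier flag.

    The automatic rule flags subjects whose |value - median| exceeds
    ``k`` times the normal-consistent MAD (1.4826 * MAD).  When the MAD is
    zero the automatic rule is disabled with a warning and only the manual
    list applies; manual exclusions are always included in the flags.
    """
    if len(values) < 5:
        raise ValueError("need at least 5 subjects for outlier screening")
    x = values.to_numpy(float)
    order = np.argsort(x)
    n = len(x)
    theoretical = stats.norm.ppf((np.arange(1, n + 1) - 0.5) / n)
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad == 0:
        warnings.warn(
            "MAD is zero; automatic outlier rule disabled, manual list only",
            stacklevel=2,
        )
        z = np.zeros(n)
    else:
        z = (x - med) / (1.4826 * mad)
    auto = set(np.asarray(values.index)[np.abs(z) > k]) if mad != 0 else set()
    flagged = sorted(auto | set(manual_exclusions))
    return QQScreenResult(
        subject_ids=list(values.index),
        theoretical=theoretical,
        ordered=x[order],
        robust_z=z,
        flagged=flagged,
    )
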