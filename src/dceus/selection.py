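"""Repeatability- and sensitivity-based feature selection.

A feature survives iff
(i)   it is repeatable on the test–retest cohort: intraclass correlation
      coefficient ICC > 0.8 (two-way, absolute-agreement, single
      measurement, on log-transformed values);
(ii)  it separates treated from control animals in the treatment-responsive
      line: unpaired Wilcoxon rank-sum p < 0.05 at each post-baseline
      imaging day;
(iii) it does NOT separate treated from control in the
      treatment-resistant line: rank-sum p > 0.1 at every day.

Criterion (ii)'s per-day requirement is configurable (``sensitivity_mode``
'all' or 'any'); the default is the stricter 'all'.  No multiple-testing
correction is applied by default, mirroring the stated thresholds; a
Benjamini–Hochberg option on the sensitivity p-values exists but is off.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.base import BaseEstimator

from dceus.features import LABEL_COLS

__all__ = [
    "SelectionThresholds",
    "SelectionResult",
    "icc_test_retest",
    "ranksum_p",
    "select_features",
    "apply_thresholds",
    "RepeatabilitySensitivitySelector",
]


@dataclass(frozen=True)
class SelectionThresholds:
    icc_min: float = 0.8
    p_sens: float = 0.05
    p_spec: float = 0.1
    sensitivity_mode: str = "all"  # 'all' days significant, or 'any'


@dataclass
class SelectionResult:
    """Full per-feature audit of the three criteria plus the kept list."""

    audit: pd.DataFrame  # per feature: icc, p_resp_d*, p_nonresp_d*, pass flags
    kept: list[str] = field(default_factory=list)
    thresholds: SelectionThresholds = field(default_factory=SelectionThresholds)

    def to_csv(self, path) -> None:
        self.audit.to_csv(path)


def _log_transform(x: np.ndarray) -> np.ndarray:
    """log(x), shifted to positive when needed (percent changes go negative)."""
    x = np.asarray(x, dtype=float)
    lo = np.nanmin(x)
    if lo > 0:
        return np.log(x)
    rng = np.nanmax(x) - lo
    eps = max(1e-8, 1e-3 * rng) if rng > 0 else 1.0
    return np.log(x - lo + eps)


def icc_test_retest(pairs, log_transform: bool = True, return_components: bool = False):
    """ICC(A,1): two-way, absolute-agreement, single-measurement ICC.

    ``pairs`` is an (n_subjects, 2) array of replicate values.  Computed
    from the standard two-way ANOVA mean squares:

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)

    with MSR the between-subject, MSC the between-replicate and MSE the
    residual mean square.  Fewer than 3 complete pairs, or zero total
    variance, yields NaN.
    """
    x = np.asarray(pairs, dtype=float)
    if x.ndim != 2 or x.shape[1] != 2:
        raise ValueError("pairs must be (n_subjects, 2)")
    x = x[np.all(np.isfinite(x), axis=1)]
    n, k = x.shape
    if n < 3:
        return (np.nan, {}) if return_components else np.nan
    if log_transform:
        x = _log_transform(x)
    grand = x.mean()
    row_m = x.mean(axis=1)
    col_m = x.mean(axis=0)
    ss_rows = k * np.sum((row_m - grand) ** 2)
    ss_cols = n * np.sum((col_m - grand) ** 2)
    ss_tot = np.sum((x - grand) ** 2)
    ss_err = ss_tot - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = max(ss_err / ((n - 1) * (k - 1)), 0.0)
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    icc = (msr - mse) / denom if abs(denom) > 1e-30 else np.nan
    if return_components:
        return icc, {"MSR": msr, "MSC": msc, "MSE": mse, "n": n, "k": k}
    return icc


def ranksum_p(group_a, group_b) -> float:
    """Two-sided unpaired Wilcoxon rank-sum (Mann–Whitney) p-value.

    Exact enumeration when the smaller group has <= 8 values and there are
    no ties; normal approximation with tie correction (and continuity
    correction) otherwise.  Completely tied data returns p = 1.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if a.size < 2 or b.size < 2:
        return np.nan
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return 1.0
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (min(a.size, b.size) <= 8 and not has_ties) else "asymptotic"
    return float(sps.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue)


def _ranksum_columns(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Column-wise two-sided rank-sum p-values; vectorized fast path.

    Columns where either group is small (exact enumeration applies), has
    missing values, or is completely tied fall back to :func:`ranksum_p`.
    """
    F = A.shape[1]
    p = np.full(F, np.nan)
    finite = np.isfinite(A).all(axis=0) & np.isfinite(B).all(axis=0)
    pooled = np.vstack([A, B])
    tied = np.all(pooled == pooled[0], axis=0)
    fast = finite & ~tied & (min(A.shape[0], B.shape[0]) > 8)
    if fast.any():
        res = sps.mannwhitneyu(A[:, fast], B[:, fast], alternative="two-sided",
                               method="asymptotic", axis=0)
        p[fast] = res.pvalue
    for j in np.flatnonzero(~fast):
        p[j] = ranksum_p(A[:, j], B[:, j])
    return p


def _per_day_pvalues(table: pd.DataFrame, feats: list[str]) -> pd.DataFrame:
    days = sorted(table["day"].unique())
    out = {}
    for d in days:
        sub = table[table["day"] == d]
        A = sub[sub["arm"] == "treated"][feats].to_numpy(dtype=float)
        B = sub[sub["arm"] == "control"][feats].to_numpy(dtype=float)
        out[d] = _ranksum_columns(A, B)
    return pd.DataFrame(out, index=feats)


def select_features(
    repeat_table: pd.DataFrame,
    responder_table: pd.DataFrame,
    nonresponder_table: pd.DataFrame,
    thresholds: SelectionThresholds | None = None,
    log_transform_icc: bool = True,
) -> SelectionResult:
    """Run the three-criterion selection on percent-change feature tables.

    ``repeat_table`` holds the test–retest cohort (two replicates per
    subject, absolute values); the responder/non-responder tables hold
    percent-change values with 'treated'/'control' arm labels per day.
    Every catalog feature appears in the audit with its criterion values or
    explicit NaN flags.
    """
    thr = thresholds or SelectionThresholds()
    for tab, name in ((repeat_table, "repeat"), (responder_table, "responder"),
                      (nonresponder_table, "nonresponder")):
        if tab is None or len(tab) == 0:
            raise ValueError(f"missing {name} cohort table")
    feats = [c for c in responder_table.columns if c not in LABEL_COLS]

    # (i) repeatability on cohort C (one wide pivot, then per-feature ICC)
    rep = repeat_table.sort_values(["subject", "replicate"])
    piv = rep.pivot_table(index="subject", columns="replicate", values=feats,
                          aggfunc="first")
    icc_vals = np.full(len(feats), np.nan)
    reps = sorted({c[1] for c in piv.columns})[:2]
    if len(reps) == 2:
        for i, f in enumerate(feats):
            try:
                x = piv[[(f, reps[0]), (f, reps[1])]].to_numpy(dtype=float)
            except KeyError:
                continue
            icc_vals[i] = icc_test_retest(x, log_transform=log_transform_icc)

    # (ii) sensitivity on responders, (iii) specificity on non-responders
    p_resp = _per_day_pvalues(responder_table, feats)
    p_nonresp = _per_day_pvalues(nonresponder_table, feats)

    audit = pd.DataFrame(index=pd.Index(feats, name="feature"))
    audit["icc"] = icc_vals
    for d in p_resp.columns:
        audit[f"p_responder_d{d}"] = p_resp[d]
    for d in p_nonresp.columns:
        audit[f"p_nonresponder_d{d}"] = p_nonresp[d]

    result = apply_thresholds(audit, thr)
    return result


def apply_thresholds(audit: pd.DataFrame, thresholds: SelectionThresholds) -> SelectionResult:
    """Recompute pass flags and the kept list from an existing audit table.

    Selection is monotone in the thresholds: raising ``icc_min`` or
    lowering ``p_sens`` (or raising ``p_spec``... lowering the allowance)
    can only remove features.
    """
    audit = audit.copy()
    resp_cols = [c for c in audit.columns if c.startswith("p_responder_")]
    nonresp_cols = [c for c in audit.columns if c.startswith("p_nonresponder_")]
    pass_icc = audit["icc"].to_numpy() > thresholds.icc_min
    p_r = audit[resp_cols].to_numpy()
    p_n = audit[nonresp_cols].to_numpy()
    with np.errstate(invalid="ignore"):
        sig = p_r < thresholds.p_sens
        if thresholds.sensitivity_mode == "all":
            pass_sens = np.all(sig & np.isfinite(p_r), axis=1)
        elif thresholds.sensitivity_mode == "any":
            pass_sens = np.any(sig, axis=1)
        else:
            raise ValueError("sensitivity_mode must be 'all' or 'any'")
        pass_spec = np.all((p_n > thresholds.p_spec) & np.isfinite(p_n), axis=1)
    audit["pass_icc"] = pass_icc
    audit["pass_sensitivity"] = pass_sens
    audit["pass_specificity"] = pass_spec
    audit["kept"] = pass_icc & pass_sens & pass_spec
    kept = list(audit.index[audit["kept"]])
    return SelectionResult(audit=audit, kept=kept, thresholds=thresholds)


class RepeatabilitySensitivitySelector(BaseEstimator):
    """sklearn-style wrapper: fit on the three cohort tables, transform tables.

    Parameters mirror :class:`SelectionThresholds`.  After ``fit`` the
    selector exposes ``result_`` (the full audit) and ``kept_`` and its
    ``transform`` restricts any feature table to the kept columns (labels
    preserved).
    """

    def __init__(self, icc_min: float = 0.8, p_sens: float = 0.05,
                 p_spec: float = 0.1, sensitivity_mode: str = "all",
                 log_transform_icc: bool = True):
        self.icc_min = icc_min
        self.p_sens = p_sens
        self.p_spec = p_spec
        self.sensitivity_mode = sensitivity_mode
        self.log_transform_icc = log_transform_icc

    def fit(self, repeat_table, responder_table=None, nonresponder_table=None):
        thr = SelectionThresholds(self.icc_min, self.p_sens, self.p_spec,
                                  self.sensitivity_mode)
        self.result_ = select_features(repeat_table, responder_table,
                                       nonresponder_table, thr,
                                       self.log_transform_icc)
        self.kept_ = list(self.result_.kept)
        return self

    def transform(self, table: pd.DataFrame) -> pd.DataFrame:
        labels = [c for c in LABEL_COLS if c in table.columns]
        return table[labels + [f for f in self.kept_ if f in table.columns]]
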