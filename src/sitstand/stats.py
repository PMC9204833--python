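"""Group-difference screening and covariate-adjusted ROC analysis.

Each candidate feature is screened with a normality-gated two-sample test
(Student's t when both groups pass a Kolmogorov-Smirnov normality check,
Wilcoxon rank-sum otherwise), its effect size quantified with Cohen's d,
and its discriminative ability with the nonparametric ROC AUC -- both
unadjusted (the Mann-Whitney estimator, ties counted half) and adjusted
for age via placement values: the marker is modelled linearly on the
covariate within controls, each case's marker is expressed relative to the
covariate-specific control distribution, and the adjusted AUC is the mean
exceedance of those placements.  Features are then gated at p < 0.05,
ranked by adjusted AUC and reported when AUC > 0.70.

No multiple-testing correction is applied by default, matching the
screen-then-rank workflow; a Benjamini-Hochberg option is available.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sst

P_THRESHOLD = 0.05
AUC_THRESHOLD = 0.70


@dataclass
class NormalityResult:
    status: str  # "normal" | "non_normal"
    p_value: float
    flagged: bool = False


@dataclass
class DiscriminationResult:
    """Screening summary for one feature under one grouping."""

    feature: str
    grouping: str
    test_used: str  # "t_test" | "wilcoxon"
    p_value: float
    cohens_d: float
    d_sign: int
    auc_adjusted: float
    auc_unadjusted: float
    n_controls: int
    n_cases: int
    flags: list[str] = field(default_factory=list)

    @property
    def passes_p(self) -> bool:
        return bool(self.p_value < P_THRESHOLD)

    @property
    def passes_auc(self) -> bool:
        return bool(self.auc_adjusted > AUC_THRESHOLD)


def normality_gate(values: np.ndarray, alpha: float = 0.05) -> NormalityResult:
    """Kolmogorov-Smirnov check against a normal with the sample moments.

    ``non_normal`` iff p < alpha.  Degenerate (constant) samples are
    non-normal by definition and flagged.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 4:
        raise ValueError("normality_gate needs at least 4 values")
    sd = values.std(ddof=1)
    if sd == 0:
        return NormalityResult("non_normal", 0.0, flagged=True)
    stat = sst.kstest(values, "norm", args=(values.mean(), sd))
    status = "non_normal" if stat.pvalue < alpha else "normal"
    return NormalityResult(status, float(stat.pvalue))


def _split(values: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    controls = values[labels == 0]
    cases = values[labels == 1]
    if controls.size < 2 or cases.size < 2:
        raise ValueError("need at least 2 observations per group")
    return controls, cases


def wilcoxon_rank_sum(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided rank-sum p via the normal approximation with tie correction."""
    res = sst.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic",
                           use_continuity=False)
    return float(res.pvalue)


def group_difference(values: np.ndarray, labels: np.ndarray) -> tuple[str, float]:
    """Normality-gated two-sample test; returns (test_used, two-sided p).

    Student's t (equal variances) when both groups pass the KS gate,
    Wilcoxon rank-sum otherwise.
    """
    controls, cases = _split(values, labels)
    if min(controls.size, cases.size) < 4:
        # too small for the normality gate; the rank test stays valid
        return "wilcoxon", wilcoxon_rank_sum(controls, cases)
    normal = (
        normality_gate(controls).status == "normal"
        and normality_gate(cases).status == "normal"
    )
    if normal:
        res = sst.ttest_ind(controls, cases, equal_var=True)
        p = float(res.pvalue)
        if np.isnan(p):  # zero pooled variance
            return "wilcoxon", wilcoxon_rank_sum(controls, cases)
        return "t_test", p
    return "wilcoxon", wilcoxon_rank_sum(controls, cases)


def cohens_d(values: np.ndarray, labels: np.ndarray) -> tuple[float, int]:
    """Cohen's d magnitude and direction.

    Pooled SD uses n-1 weights.  Returns ``(|d|, sign)`` where sign is the
    sign of (case mean - control mean); zero pooled SD yields NaN.
    """
    controls, cases = _split(values, labels)
    n0, n1 = controls.size, cases.size
    pooled = np.sqrt(
        ((n0 - 1) * controls.var(ddof=1) + (n1 - 1) * cases.var(ddof=1)) / (n0 + n1 - 2)
    )
    diff = cases.mean() - controls.mean()
    if pooled == 0:
        return float("nan"), 0
    return float(abs(diff) / pooled), int(np.sign(diff))


def unadjusted_auc(marker: np.ndarray, labels: np.ndarray) -> float:
    """Empirical Mann-Whitney AUC, ties counted one half.

    Equals the probability that a random case out-ranks a random control.
    Computed from average ranks, which reproduces the pairwise concordance
    count exactly.
    """
    controls, cases = _split(marker, labels)
    n0, n1 = controls.size, cases.size
    ranks = sst.rankdata(np.concatenate([controls, cases]))
    case_rank_sum = ranks[n0:].sum()
    u = case_rank_sum - n1 * (n1 + 1) / 2.0
    return float(u / (n0 * n1))


def _placement_auc(
    marker: np.ndarray, labels: np.ndarray, covariate: np.ndarray
) -> float:
    """Placement-value adjusted AUC with a linear control model."""
    labels = np.asarray(labels)
    marker = np.asarray(marker, dtype=float)
    covariate = np.asarray(covariate, dtype=float)
    ctrl = labels == 0
    coeffs = np.polyfit(covariate[ctrl], marker[ctrl], 1)
    resid = marker - np.polyval(coeffs, covariate)
    e0 = resid[ctrl]
    e1 = resid[~ctrl]
    exceed = (e1[:, None] > e0[None, :]).sum() + 0.5 * (e1[:, None] == e0[None, :]).sum()
    return float(exceed / (e0.size * e1.size))


def _residualized_auc(
    marker: np.ndarray, labels: np.ndarray, covariate: np.ndarray
) -> float:
    """Alternative adjustment: residualize on the pooled sample, then rank."""
    marker = np.asarray(marker, dtype=float)
    covariate = np.asarray(covariate, dtype=float)
    coeffs = np.polyfit(covariate, marker, 1)
    resid = marker - np.polyval(coeffs, covariate)
    return unadjusted_auc(resid, labels)


@dataclass
class AUCResult:
    adjusted: float
    unadjusted: float
    method: str
    flagged: bool = False


def adjusted_auc(
    marker: np.ndarray,
    labels: np.ndarray,
    covariate: np.ndarray,
    method: str = "placement",
) -> AUCResult:
    """Covariate-adjusted nonparametric AUC (plus the unadjusted value).

    ``method="placement"`` (default) standardises case markers to the
    covariate-specific control distribution; ``method="residualize"``
    regresses the marker on the covariate over the pooled sample and ranks
    the residuals.  A degenerate covariate falls back to the unadjusted
    AUC with a flag.
    """
    _split(marker, labels)  # validates group sizes
    covariate = np.asarray(covariate, dtype=float)
    if not np.all(np.isfinite(covariate)):
        raise ValueError("covariate must be finite")
    raw = unadjusted_auc(marker, labels)
    if covariate.std() < 1e-12:
        return AUCResult(adjusted=raw, unadjusted=raw, method="unadjusted", flagged=True)
    if method == "placement":
        adj = _placement_auc(marker, labels, covariate)
    elif method == "residualize":
        adj = _residualized_auc(marker, labels, covariate)
    else:
        raise ValueError(f"unknown adjustment method {method!r}")
    return AUCResult(adjusted=adj, unadjusted=raw, method=method)


def screen_feature(
    feature: str,
    values: np.ndarray,
    labels: np.ndarray,
    covariate: np.ndarray,
    grouping: str = "group",
    method: str = "placement",
) -> DiscriminationResult:
    """Full screen of one feature: gated test, Cohen's d, adjusted AUC."""
    values = np.asarray(values, dtype=float)
    flags: list[str] = []
    finite = np.isfinite(values)
    if not finite.all():
        flags.append("missing_values_dropped")
    v, l, c = values[finite], np.asarray(labels)[finite], np.asarray(covariate)[finite]
    test_used, p = group_difference(v, l)
    d, sign = cohens_d(v, l)
    if np.isnan(d):
        flags.append("zero_pooled_sd")
    auc = adjusted_auc(v, l, c, method=method)
    if auc.flagged:
        flags.append("degenerate_covariate")
    return DiscriminationResult(
        feature=feature,
        grouping=grouping,
        test_used=test_used,
        p_value=p,
        cohens_d=d,
        d_sign=sign,
        auc_adjusted=auc.adjusted,
        auc_unadjusted=auc.unadjusted,
        n_controls=int(np.sum(l == 0)),
        n_cases=int(np.sum(l == 1)),
        flags=flags,
    )


def screen_table(
    features: pd.DataFrame,
    participants: pd.DataFrame,
    grouping: str = "group",
    covariate: str = "age_years",
    method: str = "placement",
) -> pd.DataFrame:
    """Screen every feature column against one grouping column.

    ``features`` is indexed by participant id; ``participants`` carries
    the id, the binary grouping column and the covariate.
    """
    meta = participants.set_index("id").loc[features.index]
    labels = meta[grouping].to_numpy()
    cov = meta[covariate].to_numpy()
    rows = []
    for name in features.columns:
        values = features[name].to_numpy(dtype=float)
        if np.isfinite(values).sum() < 4 or len(np.unique(labels[np.isfinite(values)])) < 2:
            continue
        try:
            res = screen_feature(name, values, labels, cov, grouping=grouping, method=method)
        except ValueError:
            continue
        rows.append(
            {
                "feature": res.feature, "grouping": res.grouping,
                "test_used": res.test_used, "p_value": res.p_value,
                "cohens_d": res.cohens_d, "d_sign": res.d_sign,
                "auc_adjusted": res.auc_adjusted, "auc_unadjusted": res.auc_unadjusted,
                "n_controls": res.n_controls, "n_cases": res.n_cases,
                "passes_p": res.passes_p, "passes_auc": res.passes_auc,
            }
        )
    return pd.DataFrame(rows)


def benjamini_hochberg(p_values: np.ndarray) -> np.ndarray:
    """BH-adjusted p-values (optional, off by default in the screen)."""
    p = np.asarray(p_values, dtype=float)
    n = p.size
    order = np.argsort(p)
    adjusted = np.empty(n)
    running = 1.0
    for rank in range(n - 1, -1, -1):
        idx = order[rank]
        running = min(running, p[idx] * n / (rank + 1))
        adjusted[idx] = running
    return adjusted


def rank_features(
    results: pd.DataFrame,
    p_threshold: float = P_THRESHOLD,
    auc_threshold: float = AUC_THRESHOLD,
    apply_bh: bool = False,
) -> pd.DataFrame:
    """Screen-then-rank report: p < 0.05 gate, sort by AUC, keep AUC > 0.70."""
    if results.empty:
        return results.copy()
    out = results.copy()
    pcol = "p_value"
    if apply_bh:
        out["p_adjusted"] = benjamini_hochberg(out["p_value"].to_numpy())
        pcol = "p_adjusted"
    out = out[out[pcol] < p_threshold]
    out = out.sort_values("auc_adjusted", ascending=False, kind="mergesort")
    out = out[out["auc_adjusted"] > auc_threshold]
    return out.reset_index(drop=True)
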