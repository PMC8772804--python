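"""Paired-visit analyses: diversity stratification, fold changes, enterotype
transitions, per-feature mixed models, and paired clinical summaries.

Subjects are split at the median baseline species richness of the full
baseline cohort (low = at or below the median); the split threshold is
computed on the configured reference set because the published median derives
from all baseline samples while the paired analyses run on the follow-up
subset. Between-stratum fold-change comparisons use the two-sample rank-sum
test (two independent strata cannot be compared by a paired signed-rank
test); within-stratum change uses the Wilcoxon signed-rank test.

The visit effect on enterotype labels is tested by a chi-square on the 2 x K
baseline-vs-follow-up prevalence table, treating the two visits' label
distributions as the compared margins; a Stuart-Maxwell test on the paired
transition table is available for a stricter paired analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm

log = logging.getLogger("gutpipe")

__all__ = ["TransitionTable", "LMMResult", "stratify_by_median",
           "compare_fold_changes", "transition_test", "lmm_feature",
           "paired_clinical", "significance_stars"]


@dataclass
class TransitionTable:
    stratum: str
    counts: pd.DataFrame          # K x K, rows = V1 label, columns = V2 label

    def __post_init__(self):
        if not self.counts.index.equals(self.counts.columns):
            raise ValueError("transition table must be square over the same labels")

    @property
    def n_subjects(self) -> int:
        return int(self.counts.to_numpy().sum())

    def marginals(self) -> pd.DataFrame:
        n = self.n_subjects
        return pd.DataFrame({
            "V1": self.counts.sum(axis=1) / n,
            "V2": self.counts.sum(axis=0) / n,
        })

    def switch_summary(self, from_label: str, to_label: str) -> dict:
        """Switch fraction as numerator / denominator and rounded percent."""
        num = int(self.counts.loc[from_label, to_label])
        den = int(self.counts.loc[from_label].sum())
        pct = int(round(100.0 * num / den)) if den else 0
        return {"numerator": num, "denominator": den, "percent": pct}


@dataclass
class LMMResult:
    feature: str
    beta_time: float
    se: float
    p_value: float
    q_value: float = np.nan
    var_subject: float = np.nan
    var_lmp: float = np.nan
    var_residual: float = np.nan
    converged: bool = True
    flag: str = ""


def stratify_by_median(richness: pd.Series, reference: pd.Series | None = None) -> pd.Series:
    """Per-subject stratum from baseline richness: at/below the reference
    median -> 'low', above -> 'high'."""
    ref = richness if reference is None else reference
    if len(ref) == 0:
        raise ValueError("empty reference set for the median split")
    threshold = float(np.median(ref.to_numpy(dtype=float)))
    log.info("median richness threshold: %.1f (reference n=%d)", threshold, len(ref))
    strata = pd.Series(
        np.where(richness.to_numpy(dtype=float) <= threshold, "low", "high"),
        index=richness.index, name="stratum",
    )
    if (strata == "low").all():
        log.warning("all subjects fall in the low stratum (tied richness)")
    return strata


def compare_fold_changes(
    v1: pd.Series,
    v2: pd.Series,
    strata: pd.Series,
) -> tuple[pd.Series, dict]:
    """Per-subject fold change v2/v1 and stratum comparisons.

    Returns (fold changes, tests) where tests holds the two-sided
    between-stratum rank-sum p and within-stratum signed-rank p-values.
    Subjects with a zero baseline value are excluded and logged.
    """
    common = v1.index.intersection(v2.index)
    v1, v2 = v1.loc[common], v2.loc[common]
    zero = v1 == 0
    if zero.any():
        log.info("fold change: excluding %d subjects with zero baseline", int(zero.sum()))
        v1, v2 = v1[~zero], v2[~zero]
    fc = (v2 / v1).rename("fold_change")
    s = strata.loc[fc.index]
    out = {}
    lo, hi = fc[s == "low"], fc[s == "high"]
    if len(lo) and len(hi):
        if lo.nunique() == 1 and hi.nunique() == 1 and lo.iloc[0] == hi.iloc[0]:
            out["between_p"] = 1.0
        else:
            out["between_p"] = float(st.mannwhitneyu(lo, hi, alternative="two-sided").pvalue)
    for name, grp in (("low", lo), ("high", hi)):
        if len(grp) >= 3 and not np.allclose(grp, 1.0):
            out[f"within_{name}_p"] = float(st.wilcoxon(grp - 1.0).pvalue)
        else:
            out[f"within_{name}_p"] = np.nan
    return fc, out


def transition_test(
    labels_v1: pd.Series,
    labels_v2: pd.Series,
    stratum: str = "all",
    method: str = "marginal",
) -> tuple[TransitionTable, float, float]:
    """Enterotype transition table and visit-effect test.

    ``method='marginal'`` (default) runs a chi-square on the 2 x K table of
    V1 vs V2 label counts; ``method='stuart_maxwell'`` runs the paired
    marginal-homogeneity test on the K x K transition table.
    Returns (table, statistic, p).
    """
    common = labels_v1.index.intersection(labels_v2.index)
    if len(common) == 0:
        raise ValueError("no paired subjects between the two label sets")
    a = labels_v1.loc[common].astype(str)
    b = labels_v2.loc[common].astype(str)
    universe = sorted(set(a) | set(b))
    counts = pd.crosstab(a, b).reindex(index=universe, columns=universe, fill_value=0)
    counts.index.name, counts.columns.name = "V1", "V2"
    table = TransitionTable(stratum=stratum, counts=counts)

    if method == "marginal":
        prev = np.vstack([counts.sum(axis=1).to_numpy(), counts.sum(axis=0).to_numpy()])
        prev = prev[:, prev.sum(axis=0) > 0]
        if (a == b).all():
            return table, 0.0, 1.0
        stat, p, _, expected = st.chi2_contingency(prev, correction=False)
        if (expected < 1).mean() > 0.2:
            log.warning("transition chi-square: >20%% of expected cells < 1; "
                        "consider an exact test")
        return table, float(stat), float(p)
    if method == "stuart_maxwell":
        m = counts.to_numpy(dtype=float)
        k = m.shape[0]
        d = (m.sum(axis=1) - m.sum(axis=0))[: k - 1]
        s = np.zeros((k - 1, k - 1))
        for i in range(k - 1):
            for j in range(k - 1):
                if i == j:
                    s[i, i] = m[i].sum() + m[:, i].sum() - 2 * m[i, i]
                else:
                    s[i, j] = -(m[i, j] + m[j, i])
        try:
            stat = float(d @ np.linalg.solve(s, d))
        except np.linalg.LinAlgError:
            stat = float(d @ np.linalg.pinv(s) @ d)
        p = float(st.chi2.sf(stat, df=k - 1))
        return table, stat, p
    raise ValueError("method must be 'marginal' or 'stuart_maxwell'")


def lmm_feature(
    values,
    visit,
    subject,
    lmp=None,
    feature: str = "feature",
) -> LMMResult:
    """Random-intercept linear mixed model of one feature on visit.

    y = b0 + b1 * visit + u_subject (+ v_lmp) + e, variance components by
    REML with non-negativity enforced by the profiled optimizer. When the LMP
    factor has fewer than two levels it is silently dropped to the
    subject-only model (logged).
    """
    df = pd.DataFrame({
        "y": np.asarray(values, dtype=float),
        "visit": np.asarray([1.0 if v in (1, "V2", True) else 0.0 for v in visit]),
        "subject": np.asarray(subject).astype(str),
    })
    if df["subject"].value_counts().ge(2).sum() < 2:
        raise ValueError("need >= 2 subjects with both visits")
    if np.allclose(df["y"], df["y"].iloc[0]):
        return LMMResult(feature=feature, beta_time=0.0, se=0.0, p_value=np.nan,
                         var_subject=0.0, var_residual=0.0, flag="degenerate")
    use_lmp = False
    if lmp is not None:
        df["lmp"] = np.asarray(lmp).astype(str)
        if df["lmp"].nunique() >= 2:
            use_lmp = True
        else:
            log.info("lmm_feature(%s): LMP factor has < 2 levels; subject-only model", feature)

    exog = sm.add_constant(df[["visit"]].to_numpy())
    flag = ""

    def _ols_boundary():
        # at the variance-component boundary (subject variance 0) the REML
        # solution coincides with ordinary least squares
        ols = sm.OLS(df["y"].to_numpy(), exog).fit()
        return LMMResult(
            feature=feature, beta_time=float(ols.params[1]), se=float(ols.bse[1]),
            p_value=float(2 * st.norm.sf(abs(ols.params[1] / ols.bse[1]))),
            var_subject=0.0, var_lmp=np.nan if lmp is None else 0.0,
            var_residual=float(ols.scale), converged=True, flag="boundary-ols")

    import warnings as _warnings

    try:
        # convergence is reported through the result flag, not the warning stream
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")
            if use_lmp:
                df["one"] = 1
                vcs = {"subject": "0 + C(subject)", "lmp": "0 + C(lmp)"}
                model = sm.MixedLM.from_formula(
                    "y ~ visit", groups="one", vc_formula=vcs, data=df)
                res = model.fit(reml=True, method="lbfgs", maxiter=200)
                names = list(model.exog_vc.names)
                var_subject = float(res.vcomp[names.index("subject")])
                var_lmp = float(res.vcomp[names.index("lmp")])
                idx = res.model.exog_names.index("visit")
            else:
                model = sm.MixedLM(df["y"], exog, groups=df["subject"])
                res = model.fit(reml=True, method="lbfgs", maxiter=200)
                var_subject = float(res.cov_re.iloc[0, 0])
                var_lmp = np.nan
                idx = 1
            converged = bool(res.converged)
        beta = float(np.asarray(res.params)[idx])
        se = float(np.asarray(res.bse)[idx])
        p = float(2 * st.norm.sf(abs(beta / se))) if se > 0 else np.nan
        var_resid = float(res.scale)
    except (np.linalg.LinAlgError, ValueError) as exc:
        # singular random-effects covariance: variance component at zero
        log.info("lmm_feature(%s): %s; refitting at the OLS boundary", feature, exc)
        return _ols_boundary()
    except Exception as exc:  # noqa: BLE001 - surfaced via flag, not silenced
        log.warning("lmm_feature(%s): %s", feature, exc)
        return LMMResult(feature=feature, beta_time=np.nan, se=np.nan, p_value=np.nan,
                         converged=False, flag=f"error: {exc}")
    if not np.isfinite(se) or se == 0:
        return _ols_boundary()
    if not converged:
        flag = "non-converged"
    return LMMResult(feature=feature, beta_time=beta, se=se, p_value=p,
                     var_subject=max(var_subject, 0.0), var_lmp=var_lmp,
                     var_residual=var_resid, converged=converged, flag=flag)


def significance_stars(p: float) -> str:
    if not np.isfinite(p):
        return "ns"
    for thr, stars in ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (5e-2, "*")):
        if p <= thr:
            return stars
    return "ns"


def paired_clinical(clinical: pd.DataFrame, variables=None) -> pd.DataFrame:
    """Paired t-tests of clinical variables between V1 and V2.

    Returns one row per variable: mean V1, mean V2, paired-t p, star coding
    (ns/*/**/***/**** at 0.05/0.01/0.001/0.0001). Variables with fewer than
    three complete pairs are skipped.
    """
    v1 = clinical[clinical["visit"] == "V1"].set_index("subject_id")
    v2 = clinical[clinical["visit"] == "V2"].set_index("subject_id")
    paired = v1.index.intersection(v2.index)
    if variables is None:
        variables = [c for c in clinical.columns
                     if c not in ("subject_id", "visit", "sex", "center", "obesity_class")
                     and pd.api.types.is_numeric_dtype(clinical[c])
                     and clinical[c].dtype != bool]
    rows = []
    for var in variables:
        a = v1.loc[paired, var].astype(float)
        b = v2.loc[paired, var].astype(float)
        ok = a.notna() & b.notna()
        if ok.sum() < 3:
            log.info("paired_clinical: skipping %s (<3 pairs)", var)
            continue
        if np.allclose(a[ok], b[ok]):
            t, p = 0.0, 1.0
        else:
            t, p = st.ttest_rel(a[ok], b[ok])
        rows.append({
            "variable": var, "mean_V1": float(a[ok].mean()), "mean_V2": float(b[ok].mean()),
            "t": float(t), "p_value": float(p), "stars": significance_stars(float(p)),
            "n_pairs": int(ok.sum()),
        })
    cols = ["variable", "mean_V1", "mean_V2", "t", "p_value", "stars", "n_pairs"]
    return pd.DataFrame(rows, columns=cols).set_index("variable")
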