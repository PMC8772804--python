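"""Cross-sectional association statistics.

Adjusted linear and logistic regressions of diversity indices and enterotype
status on clinical covariates, Kruskal-Wallis / Dunn / Cliff's-delta
enrichment of features across enterotypes, and Benjamini-Hochberg control.

A note on "relative risk": the logistic models report exp(beta) per unit of
the covariate and call it a relative risk, following the convention of the
analysis this pipeline reproduces. Formally exp(beta) from logistic
regression is an odds ratio; for an outcome with ~20% prevalence the two
differ, and we keep the published operationalization rather than silently
replacing it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import PerfectSeparationError

log = logging.getLogger("gutpipe")

__all__ = ["AssociationResult", "linear_assoc", "logistic_assoc",
           "enterotype_feature_enrichment", "bh_adjust", "cliffs_delta", "dunn_test"]


@dataclass
class AssociationResult:
    outcome: str
    covariate: str
    beta: float
    se: float
    p_value: float
    beta_std: float = np.nan
    q_value: float = np.nan
    rr: float = np.nan              # exp(beta), logistic models only
    rr_ci: tuple = (np.nan, np.nan)
    adjustment: tuple = ()
    n_used: int = 0
    flag: str = ""


def _expand(data: pd.DataFrame, cols) -> pd.DataFrame:
    """Treatment-coded design block for a list of columns (categoricals to
    indicator contrasts against their first level)."""
    blocks = []
    for c in cols:
        s = data[c]
        if s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype) or s.dtype == bool:
            d = pd.get_dummies(s.astype(str), prefix=c, drop_first=True, dtype=float)
            blocks.append(d)
        else:
            blocks.append(s.astype(float).to_frame(c))
    return pd.concat(blocks, axis=1) if blocks else pd.DataFrame(index=data.index)


def _check_rank(design: pd.DataFrame) -> None:
    x = design.to_numpy(dtype=float)
    if np.linalg.matrix_rank(x) < x.shape[1]:
        # name columns whose removal restores full rank
        collinear = []
        for j, c in enumerate(design.columns):
            rest = np.delete(x, j, axis=1)
            if np.linalg.matrix_rank(rest) == np.linalg.matrix_rank(x):
                collinear.append(c)
        raise ValueError(f"rank-deficient design; collinear columns: {collinear}")


def _prepare(data, y, x, adjust):
    cols = [y, x] + list(adjust)
    sub = data[cols].dropna()
    dropped = len(data) - len(sub)
    if dropped:
        log.info("dropped %d rows with missing values for %s ~ %s", dropped, y, x)
    design = pd.concat([_expand(sub, [x]), _expand(sub, list(adjust))], axis=1)
    _check_rank(sm.add_constant(design))
    return sub, design


def linear_assoc(
    data: pd.DataFrame,
    y: str,
    x: str,
    adjust=(),
    standardize: bool = False,
) -> AssociationResult:
    """OLS of y on x with adjustment covariates; two-tailed Wald p.

    With ``standardize``, y and a numeric x are z-scored before fitting so the
    coefficient is a standardized beta.
    """
    sub, design = _prepare(data, y, x, adjust)
    yv = sub[y].astype(float)
    xname = design.columns[0]
    if standardize:
        yv = (yv - yv.mean()) / yv.std(ddof=0)
        if design[xname].nunique() > 2:
            design[xname] = (design[xname] - design[xname].mean()) / design[xname].std(ddof=0)
    model = sm.OLS(yv.to_numpy(), sm.add_constant(design.to_numpy(dtype=float)))
    res = model.fit()
    j = 1  # first column after the intercept is the x term
    return AssociationResult(
        outcome=y, covariate=x, beta=float(res.params[j]), se=float(res.bse[j]),
        p_value=float(res.pvalues[j]),
        beta_std=float(res.params[j]) if standardize else np.nan,
        adjustment=tuple(adjust), n_used=len(sub),
    )


def logistic_assoc(
    data: pd.DataFrame,
    y: str,
    x: str,
    adjust=(),
    ci_level: float = 0.95,
) -> AssociationResult:
    """Maximum-likelihood logistic regression of a binary outcome on x.

    exp(beta) per unit x is reported on the relative-risk scale (see module
    docstring). Quasi-complete separation yields a flagged result, not a
    silent estimate.
    """
    sub, design = _prepare(data, y, x, adjust)
    yv = sub[y].astype(float).to_numpy()
    if set(np.unique(yv)) - {0.0, 1.0}:
        raise ValueError("logistic outcome must be binary 0/1")
    if len(np.unique(yv)) < 2:
        raise ValueError("logistic outcome has a single class")
    flag = ""
    xmat = sm.add_constant(design.to_numpy(dtype=float))
    try:
        res = sm.Logit(yv, xmat).fit(disp=False, maxiter=200)
        if not res.mle_retvals.get("converged", True):
            flag = "non-converged"
    except PerfectSeparationError:
        flag = "separation"
        res = sm.Logit(yv, xmat).fit_regularized(disp=False, alpha=1e-6, maxiter=500)
    beta = float(np.asarray(res.params)[1])
    try:
        se = float(np.asarray(res.bse)[1])
        p = float(np.asarray(res.pvalues)[1])
    except Exception:
        se, p = np.nan, np.nan
    if not flag and (abs(beta) > 15 or not np.isfinite(se) or se > 1e3):
        flag = "separation"
    z = st.norm.ppf(0.5 + ci_level / 2)
    return AssociationResult(
        outcome=y, covariate=x, beta=beta, se=se, p_value=p,
        rr=float(np.exp(beta)),
        rr_ci=(float(np.exp(beta - z * se)), float(np.exp(beta + z * se))),
        adjustment=tuple(adjust), n_used=len(sub), flag=flag,
    )


def predicted_probability_curve(result_data: pd.DataFrame, y: str, x: str, adjust=(),
                                n_points: int = 100) -> pd.DataFrame:
    """Predicted P(y=1) over the observed x range at mean/mode adjustment values."""
    sub, design = _prepare(result_data, y, x, adjust)
    yv = sub[y].astype(float).to_numpy()
    xmat = sm.add_constant(design.to_numpy(dtype=float))
    res = sm.Logit(yv, xmat).fit(disp=False, maxiter=200)
    grid = np.linspace(design.iloc[:, 0].min(), design.iloc[:, 0].max(), n_points)
    base = design.mean(axis=0).to_numpy()
    rows = np.tile(base, (n_points, 1))
    rows[:, 0] = grid
    prob = res.predict(sm.add_constant(rows, has_constant="add"))
    return pd.DataFrame({x: grid, "p_hat": prob})


# ---------------------------------------------------------------------------
# nonparametric enrichment
# ---------------------------------------------------------------------------

def cliffs_delta(a, b) -> float:
    """Cliff's delta: (#{a > b} - #{a < b}) / (n_a * n_b) over all pairs."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    gt = (a[:, None] > b[None, :]).sum()
    lt = (a[:, None] < b[None, :]).sum()
    return float(gt - lt) / (len(a) * len(b))


def dunn_test(values: np.ndarray, groups: np.ndarray, pair: tuple) -> tuple[float, float]:
    """Dunn z-test (rank sums with tie correction) for one pair of groups.

    Returns (z, two-sided p).
    """
    n = len(values)
    ranks = st.rankdata(values)
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (12.0 * (n - 1))
    a, b = pair
    ra = ranks[groups == a]
    rb = ranks[groups == b]
    var = (n * (n + 1) / 12.0 - tie_term) * (1.0 / len(ra) + 1.0 / len(rb))
    z = (ra.mean() - rb.mean()) / np.sqrt(var)
    return float(z), float(2 * st.norm.sf(abs(z)))


def enterotype_feature_enrichment(
    features: pd.DataFrame,
    labels: pd.Series,
    focus: str = "Bact2",
) -> pd.DataFrame:
    """Per-feature enrichment of the focus enterotype against all others.

    For each feature: Kruskal-Wallis across all enterotype groups (BH across
    features), then Dunn z-tests and Cliff's delta for focus-vs-each-other
    pairs (BH across features within each pair family). Groups with fewer
    than two samples are skipped with a warning.
    """
    labels = labels.loc[features.index]
    counts = labels.value_counts()
    usable = counts[counts >= 2].index
    skipped = counts[counts < 2].index.tolist()
    if skipped:
        log.warning("enrichment: skipping groups with <2 samples: %s", skipped)
    mask = labels.isin(usable)
    feats = features.loc[mask]
    labs = labels.loc[mask].to_numpy()
    others = [g for g in usable if g != focus]
    if focus not in set(usable) or not others:
        raise ValueError("need the focus group and at least one other group with >= 2 samples")

    rows = []
    for feat in feats.columns:
        v = feats[feat].to_numpy(dtype=float)
        by_group = [v[labs == g] for g in usable]
        if np.all(v == v[0]):
            # constant feature: no evidence of any group difference
            kw_stat, kw_p = 0.0, 1.0
        else:
            kw_stat, kw_p = st.kruskal(*by_group)
        row = {"feature": feat, "kw_stat": kw_stat, "kw_p": kw_p}
        for g in others:
            if np.all(v == v[0]):
                z, p, delta = 0.0, 1.0, 0.0
            else:
                z, p = dunn_test(v, labs, (focus, g))
                delta = cliffs_delta(v[labs == focus], v[labs == g])
            row[f"dunn_z_{g}"] = z
            row[f"dunn_p_{g}"] = p
            row[f"cliffs_delta_{g}"] = delta
        rows.append(row)
    out = pd.DataFrame(rows).set_index("feature")
    out["kw_q"] = bh_adjust(out["kw_p"].to_numpy())
    for g in others:
        out[f"dunn_q_{g}"] = bh_adjust(out[f"dunn_p_{g}"].to_numpy())
    return out


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values: q_i = min over j with p_j >= p_i
    of min(1, m p_j / rank_j)."""
    p = np.asarray(p, dtype=float)
    if p.size and ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]
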