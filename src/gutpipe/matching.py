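"""Propensity-score construction and 1:1 matching with balance diagnostics.

The propensity score is the modelled probability of being in the treatment
arm (LMP supplement intake) given covariates; matching is greedy 1:1 nearest
neighbor on the logit-PS scale, without replacement, treated units processed
in descending PS order. The published design reports equal-sized exhaustive
groups, which forces without-replacement semantics; with more treated than
control subjects every control ends up matched and the group size equals the
control-arm size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

log = logging.getLogger("gutpipe")

__all__ = ["MatchResult", "propensity_match", "standardized_mean_difference"]


@dataclass
class MatchResult:
    pairs: pd.DataFrame            # treated_id, control_id, ps_distance
    unmatched: list
    balance: pd.DataFrame          # per-covariate SMD before/after
    propensity: pd.Series          # per-subject fitted PS

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)


def standardized_mean_difference(x_treated, x_control) -> float:
    """SMD = (mean_t - mean_c) / pooled SD (absolute value)."""
    a = np.asarray(x_treated, dtype=float)
    b = np.asarray(x_control, dtype=float)
    pooled = np.sqrt((a.var(ddof=1) + b.var(ddof=1)) / 2)
    if pooled == 0:
        return 0.0
    return float(abs(a.mean() - b.mean()) / pooled)


def _numeric_design(data: pd.DataFrame, covariates) -> pd.DataFrame:
    blocks = []
    for c in covariates:
        s = data[c]
        if s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype) or s.dtype == bool:
            blocks.append(pd.get_dummies(s.astype(str), prefix=c, drop_first=True, dtype=float))
        else:
            blocks.append(s.astype(float).to_frame(c))
    return pd.concat(blocks, axis=1)


def propensity_match(
    clinical: pd.DataFrame,
    treatment: str = "LMP",
    covariates=("age", "sex", "weight"),
    caliper: float | None = None,
    id_column: str = "subject_id",
) -> MatchResult:
    """Greedy 1:1 propensity matching of treated to control subjects.

    A logistic propensity model on the stated covariates yields logit-PS
    values; treated units are processed in descending PS order and matched to
    the nearest unmatched control, ties broken by subject-id order. A caliper,
    if given, is a multiple of the logit-PS standard deviation beyond which no
    match is made. Standardized mean differences before and after matching
    are reported per covariate.
    """
    cols = [id_column, treatment, *covariates]
    data = clinical[cols].dropna().reset_index(drop=True)
    t = data[treatment].astype(bool)
    if t.all() or not t.any():
        raise ValueError("both treatment groups must be non-empty")
    design = _numeric_design(data, covariates)
    x = sm.add_constant(design.to_numpy(dtype=float))
    try:
        res = sm.Logit(t.astype(float).to_numpy(), x).fit(disp=False, maxiter=200)
    except Exception as exc:
        raise ValueError(f"propensity model failed ({exc}); review covariates") from exc
    if np.abs(np.asarray(res.params)).max() > 15:
        raise ValueError("propensity model separation; review covariates")
    ps = pd.Series(res.predict(x), index=data.index, name="propensity")
    eps = 1e-12
    logit_ps = np.log((ps + eps) / (1 - ps + eps))

    treated_idx = data.index[t].tolist()
    control_idx = data.index[~t].tolist()
    # descending PS, then subject id for deterministic ties
    treated_idx.sort(key=lambda i: (-ps[i], str(data.loc[i, id_column])))
    max_dist = None
    if caliper is not None:
        max_dist = caliper * float(np.std(logit_ps, ddof=1))

    available = set(control_idx)
    pairs = []
    unmatched = []
    for i in treated_idx:
        if not available:
            unmatched.append(data.loc[i, id_column])
            continue
        cands = sorted(available, key=lambda j: (abs(logit_ps[i] - logit_ps[j]),
                                                 str(data.loc[j, id_column])))
        j = cands[0]
        dist = abs(logit_ps[i] - logit_ps[j])
        if max_dist is not None and dist > max_dist:
            unmatched.append(data.loc[i, id_column])
            continue
        available.remove(j)
        pairs.append({
            "treated_id": data.loc[i, id_column],
            "control_id": data.loc[j, id_column],
            "ps_distance": float(dist),
        })
    unmatched.extend(data.loc[sorted(available), id_column].tolist())
    pairs_df = pd.DataFrame(pairs, columns=["treated_id", "control_id", "ps_distance"])

    # balance diagnostics on numeric-expanded covariates
    matched_t = data[data[id_column].isin(pairs_df["treated_id"])].index
    matched_c = data[data[id_column].isin(pairs_df["control_id"])].index
    rows = []
    for c in design.columns:
        rows.append({
            "covariate": c,
            "smd_before": standardized_mean_difference(design.loc[t, c], design.loc[~t, c]),
            "smd_after": standardized_mean_difference(design.loc[matched_t, c],
                                                      design.loc[matched_c, c])
            if len(matched_t) else np.nan,
        })
    balance = pd.DataFrame(rows).set_index("covariate")
    ps.index = data[id_column]
    return MatchResult(pairs=pairs_df, unmatched=unmatched, balance=balance, propensity=ps)
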