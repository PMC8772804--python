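"""Diversity indices, beta-diversity, ordination, and variance decomposition.

Alpha diversity (observed richness, Shannon entropy) is computed on rarefied
species tables; beta diversity is genus-level Bray-Curtis; ordination is
classical scaling (PCoA) of the Gower-centered distance matrix; covariate
effect sizes come from distance-based redundancy analysis (dbRDA) on the
positive-eigenvalue PCoA axes with permutation tests, alongside an
Anderson-style PERMANOVA computed directly from squared distances.

No Lingoes/Cailliez correction is applied by default: constrained analyses use
only positive-eigenvalue axes, which keeps R^2 within [0, 1] and matches
common dbRDA practice.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .containers import AbundanceTable

log = logging.getLogger("gutpipe")

__all__ = [
    "DistanceMatrix", "EffectSize", "Ordination",
    "alpha_diversity", "bray_curtis", "pcoa",
    "dbrda_univariate", "dbrda_stepwise", "permanova", "permanova_stats",
]


@dataclass
class DistanceMatrix:
    """Symmetric non-negative distance matrix with zero diagonal."""

    sample_ids: list
    values: np.ndarray

    def __post_init__(self):
        d = np.asarray(self.values, dtype=float)
        if d.ndim != 2 or d.shape[0] != d.shape[1]:
            raise ValueError("distance matrix must be square")
        if not np.allclose(d, d.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(d), 0.0, atol=1e-12):
            raise ValueError("distance matrix diagonal must be zero")
        if (d < -1e-12).any():
            raise ValueError("distances must be non-negative")
        self.values = d

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.sample_ids)


@dataclass
class EffectSize:
    covariate: str
    r2: float
    adj_r2: float
    p_value: float
    n_permutations: int
    pseudo_f: float = np.nan
    cumulative_r2: float = np.nan
    cumulative_adj_r2: float = np.nan


@dataclass
class Ordination:
    sample_ids: list
    coordinates: np.ndarray       # n x m, axes with positive eigenvalues
    eigenvalues: np.ndarray       # all eigenvalues, descending
    negative_fraction: float      # |sum of negative eigenvalues| / sum |eigenvalues|


# ---------------------------------------------------------------------------
# diversity
# ---------------------------------------------------------------------------

def alpha_diversity(table: AbundanceTable) -> pd.DataFrame:
    """Observed richness S and Shannon entropy H (natural log) per sample.

    Refuses unrarefied count tables: richness estimated at unequal depths is
    not comparable across samples.
    """
    x = table.counts.to_numpy(dtype=float)
    if not table.relative:
        sums = x.sum(axis=1)
        if len(set(sums.tolist())) > 1:
            raise ValueError(
                "alpha diversity requires a rarefied table (equal row sums); "
                "rarefy first"
            )
    richness = (x > 0).sum(axis=1)
    p = x / x.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        h = -np.where(p > 0, p * np.log(p), 0.0).sum(axis=1)
    return pd.DataFrame(
        {"richness": richness, "shannon": h}, index=table.counts.index
    )


def bray_curtis(table: AbundanceTable) -> DistanceMatrix:
    """Bray-Curtis dissimilarity D_xy = 1 - sum_j min(p_xj, p_yj) on relative rows."""
    rel = table if table.relative else table.to_relative()
    x = rel.counts.to_numpy(dtype=float)
    zero = x.sum(axis=1) == 0
    if zero.any():
        bad = list(rel.counts.index[zero])
        raise ValueError(f"Bray-Curtis undefined for all-zero samples: {bad[:5]}")
    d = squareform(pdist(x, metric="braycurtis"))
    return DistanceMatrix(list(rel.counts.index), d)


# ---------------------------------------------------------------------------
# ordination
# ---------------------------------------------------------------------------

def _gower(d: np.ndarray) -> np.ndarray:
    n = d.shape[0]
    a = -0.5 * d**2
    j = np.eye(n) - np.ones((n, n)) / n
    return j @ a @ j


def pcoa(dm: DistanceMatrix, eps: float = 1e-10) -> Ordination:
    """Classical scaling of the double-centered -D^2/2 matrix.

    Coordinates are returned for positive-eigenvalue axes only (columns scaled
    by sqrt(eigenvalue)); the relative mass of negative eigenvalues is
    reported so callers can judge how non-Euclidean the distances are.
    """
    g = _gower(dm.values)
    eigval, eigvec = np.linalg.eigh(g)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    pos = eigval > eps * max(eigval.max(), 1.0)
    coords = eigvec[:, pos] * np.sqrt(eigval[pos])
    neg_mass = float(np.abs(eigval[eigval < 0]).sum())
    total_mass = float(np.abs(eigval).sum())
    return Ordination(
        sample_ids=list(dm.sample_ids),
        coordinates=coords,
        eigenvalues=eigval,
        negative_fraction=neg_mass / total_mass if total_mass > 0 else 0.0,
    )


# ---------------------------------------------------------------------------
# constrained analysis (dbRDA)
# ---------------------------------------------------------------------------

def _align(values, sample_ids):
    """Reindex a Series to the distance-matrix sample order when its index
    covers the sample ids; otherwise trust positional order."""
    if isinstance(values, pd.Series) and set(sample_ids) <= set(values.index):
        return values.loc[list(sample_ids)]
    return values


def _design(covariate: pd.Series) -> np.ndarray:
    """Column-centered design for one covariate; categoricals expand to
    treatment-coded indicators."""
    if covariate.isna().any():
        raise ValueError(f"covariate {covariate.name!r} has missing values")
    if covariate.dtype == object or isinstance(covariate.dtype, pd.CategoricalDtype) or covariate.dtype == bool:
        dummies = pd.get_dummies(covariate.astype(str), drop_first=True)
        x = dummies.to_numpy(dtype=float)
    else:
        x = covariate.to_numpy(dtype=float)[:, None]
    if x.shape[1] == 0 or np.allclose(x.std(axis=0), 0.0):
        raise ValueError(f"covariate {covariate.name!r} is constant")
    return x - x.mean(axis=0)


def _fit_stats(y: np.ndarray, x: np.ndarray) -> tuple[float, float, int]:
    """R^2, pseudo-F and rank for centered axes y regressed on centered design x."""
    n = y.shape[0]
    q, r = np.linalg.qr(x)
    rank = int(np.sum(np.abs(np.diag(r)) > 1e-10 * max(1.0, np.abs(np.diag(r)).max())))
    q = q[:, :rank]
    total = float((y**2).sum())
    fitted = float(((q.T @ y) ** 2).sum())
    r2 = fitted / total
    df_res = n - rank - 1
    f = (fitted / rank) / ((total - fitted) / df_res) if df_res > 0 else np.inf
    return r2, f, rank


def _ezekiel(r2: float, n: int, p: int) -> float:
    if n - p - 1 <= 0:
        return np.nan
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


def dbrda_univariate(
    dm: DistanceMatrix,
    covariate: pd.Series,
    n_permutations: int = 999,
    seed: int = 0,
    ordination: Ordination | None = None,
) -> EffectSize:
    """Fraction of beta-diversity inertia explained by one covariate.

    Redundancy analysis of the positive-eigenvalue PCoA axes on the covariate
    design; significance by permuting covariate rows against the pseudo-F
    statistic, p floored at 1/(n_permutations + 1).
    """
    ord_ = ordination if ordination is not None else pcoa(dm)
    y = ord_.coordinates - ord_.coordinates.mean(axis=0)
    x = _design(_align(covariate, dm.sample_ids))
    n = y.shape[0]
    r2, f_obs, rank = _fit_stats(y, x)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        _, f_perm, _ = _fit_stats(y, x[perm])
        if f_perm >= f_obs:
            hits += 1
    p = (1 + hits) / (n_permutations + 1)
    return EffectSize(
        covariate=str(covariate.name), r2=r2, adj_r2=_ezekiel(r2, n, rank),
        p_value=p, n_permutations=n_permutations, pseudo_f=f_obs,
    )


def dbrda_stepwise(
    dm: DistanceMatrix,
    covariates: pd.DataFrame,
    alpha_in: float = 0.05,
    n_permutations: int = 999,
    seed: int = 0,
) -> list[EffectSize]:
    """Forward selection of covariates on dbRDA adjusted R^2.

    At each step the candidate with the highest cumulative adjusted R^2 is
    added if its partial permutation p-value is <= alpha_in and the cumulative
    adjusted R^2 does not exceed the full-model adjusted R^2 (the standard
    double stopping rule in ordination model building). Returns one cumulative
    EffectSize per accepted step; the list may be empty.
    """
    if covariates.shape[1] < 2:
        raise ValueError("stepwise selection needs >= 2 candidate covariates")
    ord_ = pcoa(dm)
    y = ord_.coordinates - ord_.coordinates.mean(axis=0)
    n = y.shape[0]
    rng = np.random.default_rng(seed)

    designs = {c: _design(_align(covariates[c], dm.sample_ids)) for c in covariates.columns}
    full_x = np.hstack(list(designs.values()))
    full_r2, _, full_rank = _fit_stats(y, full_x)
    full_adj = _ezekiel(full_r2, n, full_rank)

    selected: list[str] = []
    results: list[EffectSize] = []
    current_x = np.empty((n, 0))
    current_r2, current_rank = 0.0, 0
    while True:
        candidates = [c for c in covariates.columns if c not in selected]
        if not candidates:
            break
        best = None
        for c in candidates:
            xc = np.hstack([current_x, designs[c]])
            r2, _, rank = _fit_stats(y, xc)
            if rank == current_rank:
                continue  # candidate is collinear with the selected set
            adj = _ezekiel(r2, n, rank)
            if best is None or adj > best[1]:
                best = (c, adj, r2, rank)
        if best is None:
            break
        c, adj, r2, rank = best
        if adj > full_adj + 1e-12:
            break
        # partial permutation test for the added term
        q_add = rank - current_rank
        denom_df = n - rank - 1
        f_obs = ((r2 - current_r2) / q_add) / ((1 - r2) / denom_df)
        hits = 0
        for _ in range(n_permutations):
            perm = rng.permutation(n)
            xp = np.hstack([current_x, designs[c][perm]])
            r2p, _, rankp = _fit_stats(y, xp)
            qp = max(rankp - current_rank, 1)
            fp = ((r2p - current_r2) / qp) / ((1 - r2p) / (n - rankp - 1))
            if fp >= f_obs:
                hits += 1
        p = (1 + hits) / (n_permutations + 1)
        if p > alpha_in:
            break
        selected.append(c)
        current_x = np.hstack([current_x, designs[c]])
        current_r2, current_rank = r2, rank
        results.append(EffectSize(
            covariate=c, r2=r2 - (results[-1].cumulative_r2 if results else 0.0),
            adj_r2=adj, p_value=p, n_permutations=n_permutations, pseudo_f=f_obs,
            cumulative_r2=r2, cumulative_adj_r2=adj,
        ))
    return results


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

def permanova_stats(d2: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """(R^2, pseudo-F) of the Anderson partition of squared distances."""
    n = d2.shape[0]
    groups, counts = np.unique(labels, return_counts=True)
    a = len(groups)
    if a < 2:
        raise ValueError("PERMANOVA needs at least two groups")
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for g, ng in zip(groups, counts):
        idx = np.flatnonzero(labels == g)
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(ng, 1)].sum() / ng
    ss_between = ss_total - ss_within
    f = (ss_between / (a - 1)) / (ss_within / (n - a))
    return ss_between / ss_total, f


def permanova(
    dm: DistanceMatrix,
    group: pd.Series | np.ndarray,
    strata: pd.Series | np.ndarray | None = None,
    n_permutations: int = 999,
    seed: int = 0,
) -> dict:
    """Permutational multivariate ANOVA on a distance matrix.

    p = (1 + #{permuted F >= observed F}) / (n_permutations + 1). When
    ``strata`` is given, labels are permuted within strata only (used for
    paired designs where permutations are restricted within subjects).
    """
    labels = np.asarray(_align(group, dm.sample_ids))
    if len(labels) != dm.n:
        raise ValueError("group labels must cover all samples")
    if len(np.unique(labels)) < 2:
        raise ValueError("group labels identical across samples: pseudo-F undefined")
    d2 = dm.values**2
    r2, f_obs = permanova_stats(d2, labels)

    strata_arr = None
    if strata is not None:
        strata_arr = np.asarray(_align(strata, dm.sample_ids))
        _, scounts = np.unique(strata_arr, return_counts=True)
        if (scounts < 2).any():
            log.warning("permanova: %d strata hold a single sample and cannot permute",
                        int((scounts < 2).sum()))

    rng = np.random.default_rng(seed)
    n = dm.n
    hits = 0
    for _ in range(n_permutations):
        if strata_arr is None:
            perm_labels = labels[rng.permutation(n)]
        else:
            perm_labels = labels.copy()
            for s in np.unique(strata_arr):
                idx = np.flatnonzero(strata_arr == s)
                perm_labels[idx] = labels[idx[rng.permutation(len(idx))]]
        _, f_perm = permanova_stats(d2, perm_labels)
        if f_perm >= f_obs:
            hits += 1
    p = (1 + hits) / (n_permutations + 1)
    return {"r2": r2, "pseudo_f": f_obs, "p_value": p, "n_permutations": n_permutations}
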