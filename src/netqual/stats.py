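"""Group inference for GTA profiles and connectivity matrices.

Permutation tests (difference of group means, two-sided, add-one p-value
estimator), covariate residualization by pooled ordinary least squares,
permutation tests on regression coefficients, Pearson cognition correlations
with Dunn-Sidak familywise correction, edgewise comparisons with Cohen's d,
and pooled-variance two-sample t-tests from summary statistics.

All randomness flows through explicit seeds; permutation label assignments
are shared across the (metric, threshold) cells of one comparison call, which
keeps the whole scan reproducible and fast (the permutation means reduce to a
single matrix product).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as spstats

__all__ = [
    "StatsConfig",
    "PermutationResult",
    "TTestResult",
    "EdgewiseResult",
    "dunn_sidak",
    "permutation_test",
    "residualize",
    "gta_group_comparison",
    "covariate_contribution",
    "cognition_correlations",
    "edgewise_comparison",
    "t_test_from_summary",
]

COGNITIVE_SCORES = ("sdmt", "cvlt", "bvmt", "cowat", "fsmc",
                    "bicams_scaled", "bicams_z")


@dataclass
class StatsConfig:
    alpha: float = 0.05
    n_perm: int = 10_000
    seed: int = 0
    m_comparisons: int | None = None   # Dunn-Sidak family size; None = derive

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.n_perm < 1:
            raise ValueError("n_perm must be positive")


@dataclass
class PermutationResult:
    observed_diff: float
    p: float
    n_perm: int
    seed: int


@dataclass
class TTestResult:
    t: float
    df: int
    p: float
    test: str = "pooled-variance"


@dataclass
class EdgewiseResult:
    """Edge-by-edge permutation p-values and effect sizes.

    ``p`` and ``d`` are symmetric node x node matrices (diagonal 0); ``d`` is
    Cohen's d with pooled sd, second group minus first.  ``mean_fc`` holds the
    overall mean functional connectivity (raw Pearson r over all edges and
    subjects) per group.
    """

    p: np.ndarray
    d: np.ndarray
    mean_fc: dict[str, float]
    groups: tuple[str, str]
    n_perm: int


def dunn_sidak(alpha: float, m: int) -> float:
    """Familywise-corrected per-comparison alpha: 1 - (1 - alpha)^(1/m)."""
    if m < 1:
        raise ValueError(f"number of comparisons must be >= 1, got {m}")
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    return 1.0 - (1.0 - alpha) ** (1.0 / m)


def _perm_signs(n: int, n_b: int, n_perm: int,
                rng: np.random.Generator) -> np.ndarray:
    """(n_perm, n) matrix M with M @ v = mean(v[perm B]) - mean(v[perm A])."""
    u = rng.random((n_perm, n))
    order = np.argsort(u, axis=1)
    in_b = np.zeros((n_perm, n), dtype=bool)
    np.put_along_axis(in_b, order[:, :n_b], True, axis=1)
    n_a = n - n_b
    return np.where(in_b, 1.0 / n_b, -1.0 / n_a)


def _perm_pvalues(values: np.ndarray, in_b: np.ndarray, n_perm: int,
                  rng: np.random.Generator):
    """Two-sided permutation p for each row of ``values`` (cells x subjects).

    Statistic: mean over group B minus mean over group A.  Permutations are
    shared across rows.  Returns (observed, p).
    """
    v = np.atleast_2d(np.asarray(values, dtype=float))
    in_b = np.asarray(in_b, dtype=bool)
    n = in_b.size
    n_b = int(in_b.sum())
    if n_b == 0 or n_b == n:
        raise ValueError("both groups must be non-empty")
    obs = v[:, in_b].mean(axis=1) - v[:, ~in_b].mean(axis=1)
    signs = _perm_signs(n, n_b, n_perm, rng)
    diffs = v @ signs.T                      # cells x n_perm
    exceeds = np.abs(diffs) >= np.abs(obs)[:, None] - 1e-12
    p = (1.0 + exceeds.sum(axis=1)) / (n_perm + 1.0)
    return obs, p


def permutation_test(a, b, n_perm: int = 10_000, seed: int = 0) -> PermutationResult:
    """Two-sided permutation test on the difference of group means.

    Statistic: mean(a) - mean(b).  Group labels are shuffled preserving group
    sizes; p uses the add-one estimator (1 + b) / (1 + n_perm), so the
    smallest attainable p is 1/(n_perm + 1).
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    values = np.concatenate([a, b])[None, :]
    in_a = np.zeros(a.size + b.size, dtype=bool)
    in_a[:a.size] = True
    rng = np.random.default_rng(seed)
    obs, p = _perm_pvalues(values, in_a, n_perm, rng)
    return PermutationResult(observed_diff=float(obs[0]), p=float(p[0]),
                             n_perm=n_perm, seed=seed)


def _design(covariates: np.ndarray, names: list[str]) -> np.ndarray:
    x = np.column_stack([np.ones(covariates.shape[0]), covariates])
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        collinear = []
        for j in range(covariates.shape[1]):
            reduced = np.delete(x, j + 1, axis=1)
            if np.linalg.matrix_rank(reduced) == rank:
                collinear.append(names[j])
        raise ValueError(f"rank-deficient design; collinear columns: {collinear}")
    return x


def residualize(values, covariates, names: list[str] | None = None) -> np.ndarray:
    """OLS residuals of ``values`` on [intercept, covariates], grand mean restored.

    The regression pools all subjects (no group term), so any group difference
    that the covariates explain is removed from the residuals.
    """
    y = np.asarray(values, dtype=float).ravel()
    if isinstance(covariates, pd.DataFrame):
        names = list(covariates.columns)
        c = covariates.to_numpy(dtype=float)
    else:
        c = np.atleast_2d(np.asarray(covariates, dtype=float))
        if c.shape[0] != y.size:
            c = c.T
    if c.size == 0:
        return y.copy()
    if names is None:
        names = [f"x{j}" for j in range(c.shape[1])]
    if y.size <= c.shape[1] + 1:
        raise ValueError("need more subjects than covariates + 1")
    x = _design(c, names)
    fit = sm.OLS(y, x).fit()
    return np.asarray(fit.resid) + y.mean()


def _profile_cells(profiles: pd.DataFrame, subject_order: list[str]):
    """Pivot tidy profiles into (cells x subjects) with cell labels."""
    wide = profiles.pivot_table(index=["metric", "threshold"],
                                columns="subject_id", values="value")
    wide = wide[subject_order]
    return wide.index.to_list(), wide.to_numpy(dtype=float)


def gta_group_comparison(profiles: pd.DataFrame, cohort: pd.DataFrame,
                         covariates: list[str], config: StatsConfig,
                         groups: tuple[str, str] | None = None) -> pd.DataFrame:
    """Permutation group test per (metric, threshold) after residualization.

    ``profiles`` is tidy (subject_id, threshold, metric, value); ``cohort``
    provides the group labels and covariate columns.  For every cell the
    metric is residualized on the covariates (pooled OLS) and the residuals
    compared between groups.  ``observed_diff`` is second group minus first
    (sorted labels unless ``groups`` is given).
    """
    labels = cohort["group"].to_numpy()
    if groups is None:
        uniq = sorted(pd.unique(labels))
        if len(uniq) != 2:
            raise ValueError(f"need exactly two groups, found {uniq}")
        groups = (uniq[0], uniq[1])
    in_b = labels == groups[1]
    if not in_b.any() or in_b.all():
        raise ValueError(f"groups {groups} not both present")
    subject_order = cohort["subject_id"].tolist()
    cells, values = _profile_cells(profiles, subject_order)
    if covariates:
        cov = cohort[list(covariates)]
        values = np.vstack([residualize(row, cov) for row in values])
    rng = np.random.default_rng(config.seed)
    obs, p = _perm_pvalues(values, in_b, config.n_perm, rng)
    out = pd.DataFrame(cells, columns=["metric", "threshold"])
    out["covariates"] = "+".join(covariates) if covariates else "none"
    out["observed_diff"] = obs
    out["p"] = p
    out["significant"] = out["p"] < config.alpha
    return out


def covariate_contribution(profiles: pd.DataFrame, cohort: pd.DataFrame,
                           covariate_name: str, covariates: list[str],
                           config: StatsConfig) -> pd.DataFrame:
    """Permutation p-value for one covariate's regression coefficient.

    Fits value ~ intercept + covariates per (metric, threshold) cell, then
    permutes the ``covariate_name`` column across subjects, refits, and
    compares |coefficient| (implemented via Frisch-Waugh-Lovell partialling,
    which makes the permutation refits a single matrix product).
    """
    if covariate_name not in covariates:
        raise ValueError(f"{covariate_name!r} is not among the model covariates")
    others = [c for c in covariates if c != covariate_name]
    subject_order = cohort["subject_id"].tolist()
    cells, values = _profile_cells(profiles, subject_order)
    y = values.T                                        # subjects x cells
    c = cohort[covariate_name].to_numpy(dtype=float)
    if np.std(c) == 0:
        raise ValueError(f"covariate {covariate_name!r} is constant "
                         "(rank-deficient design)")
    x_other = _design(cohort[others].to_numpy(dtype=float) if others
                      else np.empty((len(c), 0)), others)
    hat = x_other @ np.linalg.pinv(x_other)
    e_obs = c - hat @ c
    coef_obs = (e_obs @ y) / (e_obs @ e_obs)
    rng = np.random.default_rng(config.seed)
    perms = np.vstack([rng.permutation(c) for _ in range(config.n_perm)])
    e_perm = perms - perms @ hat.T
    denom = np.einsum("ij,ij->i", e_perm, e_perm)
    coef_perm = (e_perm @ y) / denom[:, None]           # n_perm x cells
    exceeds = np.abs(coef_perm) >= np.abs(coef_obs)[None, :] - 1e-12
    p = (1.0 + exceeds.sum(axis=0)) / (config.n_perm + 1.0)
    out = pd.DataFrame(cells, columns=["metric", "threshold"])
    out["covariate"] = covariate_name
    out["coefficient"] = coef_obs
    out["p"] = p
    out["significant"] = out["p"] < config.alpha
    return out


def _pearson_matrix(a: np.ndarray, b: np.ndarray):
    """Pearson r between every row of a and every row of b, with t-test p."""
    az = (a - a.mean(axis=1, keepdims=True)) / a.std(axis=1, keepdims=True)
    bz = (b - b.mean(axis=1, keepdims=True)) / b.std(axis=1, keepdims=True)
    n = a.shape[1]
    r = np.clip(az @ bz.T / n, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1 - r**2, 1e-300))
    p = 2 * spstats.t.sf(np.abs(t), df=n - 2)
    return r, p


def cognition_correlations(profiles: pd.DataFrame, cohort: pd.DataFrame,
                           config: StatsConfig,
                           scores: tuple[str, ...] = COGNITIVE_SCORES
                           ) -> pd.DataFrame:
    """Pearson r between every GTA metric and cognitive score, per threshold.

    Significance uses the Dunn-Sidak-corrected alpha; the family is the set of
    (metric, score) pairs within one threshold (config.m_comparisons
    overrides).
    """
    for s in scores:
        if cohort[s].std() == 0:
            raise ValueError(f"cognitive score {s!r} is constant")
    subject_order = cohort["subject_id"].tolist()
    score_mat = cohort[list(scores)].to_numpy(dtype=float).T
    rows = []
    metrics = sorted(profiles["metric"].unique())
    m = config.m_comparisons or len(metrics) * len(scores)
    alpha_corr = dunn_sidak(config.alpha, m)
    for tau, sub in profiles.groupby("threshold"):
        wide = sub.pivot_table(index="metric", columns="subject_id",
                               values="value")[subject_order]
        r, p = _pearson_matrix(wide.to_numpy(dtype=float), score_mat)
        for i, metric in enumerate(wide.index):
            for j, score in enumerate(scores):
                rows.append({"threshold": float(tau), "metric": metric,
                             "score": score, "r": r[i, j], "p": p[i, j],
                             "significant": p[i, j] < alpha_corr})
    out = pd.DataFrame(rows)
    out.attrs["alpha_corrected"] = alpha_corr
    out.attrs["m_comparisons"] = m
    return out


def edgewise_comparison(adjacencies: np.ndarray, groups_per_subject,
                        config: StatsConfig,
                        groups: tuple[str, str] | None = None,
                        fisher: bool = True) -> EdgewiseResult:
    """Permutation test and Cohen's d for every edge weight.

    ``adjacencies``: stack (n_subjects x n x n) of Pearson matrices.  Weights
    are Fisher-z transformed before testing (variance stabilization;
    ``fisher=False`` tests raw r).  d = (mean_B - mean_A) / pooled sd.
    """
    adj = np.asarray(adjacencies, dtype=float)
    labels = np.asarray(groups_per_subject)
    if adj.ndim != 3 or adj.shape[0] != labels.size:
        raise ValueError("adjacency stack and group labels are inconsistent")
    if groups is None:
        uniq = sorted(pd.unique(labels))
        if len(uniq) != 2:
            raise ValueError(f"need exactly two groups, found {uniq}")
        groups = (uniq[0], uniq[1])
    in_b = labels == groups[1]
    n = adj.shape[1]
    iu = np.triu_indices(n, k=1)
    vals = adj[:, iu[0], iu[1]]                         # subjects x edges
    tested = np.arctanh(np.clip(vals, -0.999999, 0.999999)) if fisher else vals
    rng = np.random.default_rng(config.seed)
    _, p = _perm_pvalues(tested.T, in_b, config.n_perm, rng)
    xb, xa = tested[in_b], tested[~in_b]
    nb, na = xb.shape[0], xa.shape[0]
    pooled = np.sqrt(((nb - 1) * xb.var(axis=0, ddof=1)
                      + (na - 1) * xa.var(axis=0, ddof=1)) / (nb + na - 2))
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(pooled > 0, (xb.mean(axis=0) - xa.mean(axis=0)) / pooled, 0.0)
    p_mat = np.zeros((n, n))
    d_mat = np.zeros((n, n))
    p_mat[iu] = p
    d_mat[iu] = d
    p_mat += p_mat.T
    d_mat += d_mat.T
    mean_fc = {groups[0]: float(vals[~in_b].mean()),
               groups[1]: float(vals[in_b].mean())}
    return EdgewiseResult(p=p_mat, d=d_mat, mean_fc=mean_fc, groups=groups,
                          n_perm=config.n_perm)


def t_test_from_summary(mean1: float, sd1: float, n1: int,
                        mean2: float, sd2: float, n2: int) -> TTestResult:
    """Pooled-variance two-sample t-test from summary statistics."""
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 observations")
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("standard deviations must be positive")
    res = spstats.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2,
                                       equal_var=True)
    return TTestResult(t=float(res.statistic), df=n1 + n2 - 2,
                       p=float(res.pvalue))
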