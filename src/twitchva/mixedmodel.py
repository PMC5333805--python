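"""REML fitting of the heteroscedastic nested mixed model.

The group comparison models a response measured once per arm x posture
with fixed effects for transfer group, posture and their interaction,

    y = X beta + b_subject + b_arm + eps,

where ``b_subject`` and ``b_arm`` are random intercepts (arms nested in
subjects: some participants contributed both arms) and the residual
variance may differ between transfer groups — the groups' spreads are
visibly unequal.  Variance components are estimated by restricted
maximum likelihood over small per-subject covariance blocks; fixed
effects use sum-to-zero coding so the Wald F statistics are the usual
Type-III main effects and interaction.

Denominator degrees of freedom follow a containment-style convention
(between-arm effects: n_arms - 2; within-arm effects: N - n_arms -
2(k-1) for k postures); on balanced homoscedastic data these reproduce
the classical split-plot ANOVA exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.optimize
import scipy.stats

from .errors import ValidationError

EFFECT_TRANSFER = "transfer"
EFFECT_POSTURE = "posture"
EFFECT_INTERACTION = "interaction"


def _sum_code(values: np.ndarray, levels: list) -> np.ndarray:
    """Sum-to-zero (deviation) coding: k levels -> k-1 columns."""
    n, k = len(values), len(levels)
    cols = np.zeros((n, k - 1))
    for j, lev in enumerate(levels[:-1]):
        cols[values == lev, j] = 1.0
    cols[values == levels[-1], :] = -1.0
    return cols


@dataclass
class MixedModelFit:
    """Fitted model: fixed effects, their covariance, variance components."""

    response: str
    beta: np.ndarray
    cov_beta: np.ndarray
    variance_components: dict
    column_labels: list[str]
    group_levels: list[str]
    posture_levels: list[str]
    n_obs: int
    n_arms: int
    n_subjects: int
    df_between: int
    df_within: int
    reml_neg2loglik: float
    converged: bool
    _effect_columns: dict = field(default_factory=dict)

    def cell_row(self, group: str, posture: str) -> np.ndarray:
        """Design row whose dot with beta is the (group, posture) cell mean."""
        g = _sum_code(np.array([group]), self.group_levels)
        p = _sum_code(np.array([posture]), self.posture_levels)
        return np.concatenate([[1.0], g[0], p[0], (g[0, 0] * p[0])])

    def estimate(self, row: np.ndarray) -> tuple[float, float]:
        """Point estimate and standard error of a linear combination."""
        est = float(row @ self.beta)
        se = float(np.sqrt(row @ self.cov_beta @ row))
        return est, se

    def wald_f(self, effect: str) -> tuple[float, int, int, float]:
        """Type-III Wald F test of one effect: (F, df_num, df_den, p)."""
        idx = self._effect_columns[effect]
        b = self.beta[idx]
        c = self.cov_beta[np.ix_(idx, idx)]
        q = len(idx)
        f = float(b @ np.linalg.solve(c, b)) / q
        df_den = self.df_between if effect == EFFECT_TRANSFER else self.df_within
        p = float(scipy.stats.f.sf(f, q, df_den))
        return f, q, df_den, p


def _build_design(table: pd.DataFrame, response: str):
    y = table[response].to_numpy(dtype=float)
    groups = sorted(table["transfer_group"].unique())
    postures = sorted(table["posture"].unique())
    if len(groups) < 2:
        raise ValidationError("singular design: only one transfer group present")
    if len(postures) < 2:
        raise ValidationError("singular design: fewer than two postures present")
    g = _sum_code(table["transfer_group"].to_numpy(), groups)
    p = _sum_code(table["posture"].to_numpy(), postures)
    inter = g[:, [0]] * p
    X = np.column_stack([np.ones(len(table)), g, p, inter])
    k = len(postures)
    labels = (
        ["intercept", f"transfer[{groups[0]}]"]
        + [f"posture[{lv}]" for lv in postures[:-1]]
        + [f"transfer[{groups[0]}]:posture[{lv}]" for lv in postures[:-1]]
    )
    effect_cols = {
        EFFECT_TRANSFER: [1],
        EFFECT_POSTURE: list(range(2, 2 + (k - 1))),
        EFFECT_INTERACTION: list(range(2 + (k - 1), 2 + 2 * (k - 1))),
    }
    return y, X, groups, postures, labels, effect_cols


def _block_structure(table: pd.DataFrame, nested_subject: bool):
    """Per-block (subject or arm) observation indices and arm memberships."""
    key = "subject_id" if nested_subject else "arm_id"
    blocks = []
    for _, idx in table.groupby(key, sort=True).indices.items():
        sub = table.iloc[idx]
        arm_ids = sub["arm_id"].to_numpy()
        arm_sets = [np.flatnonzero(arm_ids == a) for a in pd.unique(arm_ids)]
        blocks.append((np.asarray(idx), arm_sets))
    return blocks


def _neg2_reml(params, y, X, blocks, resid_group_idx, n_resid, nested):
    var = np.exp(np.clip(params, -30.0, 30.0))
    if nested:
        s2_subj, s2_arm = var[0], var[1]
        resid = var[2 : 2 + n_resid]
    else:
        s2_subj, s2_arm = 0.0, var[0]
        resid = var[1 : 1 + n_resid]
    p = X.shape[1]
    xtvx = np.zeros((p, p))
    xtvy = np.zeros(p)
    ytvy = 0.0
    logdet = 0.0
    for idx, arm_sets in blocks:
        m = len(idx)
        V = np.full((m, m), s2_subj)
        for a in arm_sets:
            V[np.ix_(a, a)] += s2_arm
        V[np.diag_indices(m)] += resid[resid_group_idx[idx]]
        try:
            L = np.linalg.cholesky(V)
        except np.linalg.LinAlgError:
            return 1e12
        logdet += 2.0 * float(np.sum(np.log(np.diag(L))))
        Xb = X[idx]
        yb = y[idx]
        LiX = scipy.linalg.solve_triangular(L, Xb, lower=True)
        Liy = scipy.linalg.solve_triangular(L, yb, lower=True)
        xtvx += LiX.T @ LiX
        xtvy += LiX.T @ Liy
        ytvy += float(Liy @ Liy)
    sign, logdet_xtvx = np.linalg.slogdet(xtvx)
    if sign <= 0:
        return 1e12
    beta = np.linalg.solve(xtvx, xtvy)
    quad = ytvy - float(beta @ xtvy)
    return logdet + logdet_xtvx + quad


def fit_mixed_model(
    table: pd.DataFrame,
    response: str,
    heteroscedastic: bool = True,
    nested_subject: bool = True,
) -> MixedModelFit:
    """Fit the nested random-intercept model by REML.

    ``table`` needs columns subject_id, arm_id, transfer_group, posture
    and the response; rows with a missing response are dropped (QC
    exclusions enter as missing VA).  ``heteroscedastic=False`` pools
    the residual variance across transfer groups; ``nested_subject=
    False`` collapses the subject level so arms are independent.
    """
    tab = table.dropna(subset=[response]).reset_index(drop=True)
    y, X, groups, postures, labels, effect_cols = _build_design(tab, response)
    if nested_subject and tab.groupby("subject_id")["arm_id"].nunique().max() == 1:
        # every subject contributed one arm: the subject level is empty and
        # sigma^2_subject + sigma^2_arm would sit on an unidentifiable ridge
        nested_subject = False
    blocks = _block_structure(tab, nested_subject)

    n_resid = len(groups) if heteroscedastic else 1
    if heteroscedastic:
        gmap = {g: i for i, g in enumerate(groups)}
        resid_group_idx = tab["transfer_group"].map(gmap).to_numpy()
    else:
        resid_group_idx = np.zeros(len(tab), dtype=int)

    # moment-based start: split the OLS residual variance across components
    beta_ols, *_ = np.linalg.lstsq(X, y, rcond=None)
    s2_tot = max(float(np.var(y - X @ beta_ols, ddof=X.shape[1])), 1e-12)
    parts = ([0.2, 0.4] if nested_subject else [0.5]) + [0.6] * n_resid
    x0 = np.log(s2_tot * np.asarray(parts))

    args = (y, X, blocks, resid_group_idx, n_resid, nested_subject)
    res = scipy.optimize.minimize(
        _neg2_reml, x0, args=args, method="Nelder-Mead",
        options={"xatol": 1e-6, "fatol": 1e-9, "maxiter": 2000},
    )
    var = np.exp(np.clip(res.x, -30.0, 30.0))
    if nested_subject:
        vc = {"subject": float(var[0]), "arm": float(var[1])}
        resid = var[2:]
    else:
        vc = {"subject": 0.0, "arm": float(var[0])}
        resid = var[1:]
    if heteroscedastic:
        vc["residual"] = {g: float(v) for g, v in zip(groups, resid)}
    else:
        vc["residual"] = {g: float(resid[0]) for g in groups}

    # final GLS pass at the REML estimates
    s2_subj = vc["subject"] if nested_subject else 0.0
    s2_arm = vc["arm"]
    resid_vec = np.array([vc["residual"][g] for g in groups])[resid_group_idx]
    p = X.shape[1]
    xtvx = np.zeros((p, p))
    xtvy = np.zeros(p)
    for idx, arm_sets in blocks:
        m = len(idx)
        V = np.full((m, m), s2_subj)
        for a in arm_sets:
            V[np.ix_(a, a)] += s2_arm
        V[np.diag_indices(m)] += resid_vec[idx]
        Vi = np.linalg.inv(V)
        xtvx += X[idx].T @ Vi @ X[idx]
        xtvy += X[idx].T @ Vi @ y[idx]
    cov_beta = np.linalg.inv(xtvx)
    beta = cov_beta @ xtvy

    n_arms = tab["arm_id"].nunique()
    k = len(postures)
    return MixedModelFit(
        response=response,
        beta=beta,
        cov_beta=cov_beta,
        variance_components=vc,
        column_labels=labels,
        group_levels=groups,
        posture_levels=postures,
        n_obs=len(tab),
        n_arms=n_arms,
        n_subjects=tab["subject_id"].nunique(),
        df_between=max(n_arms - 2, 1),
        df_within=max(len(tab) - n_arms - 2 * (k - 1), 1),
        reml_neg2loglik=float(res.fun),
        converged=bool(res.success),
        _effect_columns=effect_cols,
    )
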