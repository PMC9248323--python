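"""Group-level statistics.

Covers the statistical toolkit of the analysis: principal component
analysis with sampling-adequacy checks (KMO, Bartlett sphericity), varimax
rotation and regression-method component scores; ANCOVA with sum-to-zero
(Type III) coding, group-by-segment and group-by-covariate interactions and
simple-slopes moderation; Spearman and partial-Spearman correlation
families with Bonferroni correction; ±3 SD within-group outlier screening;
the |r| > 0.3 covariate screen; and the disease burden score
DBS = age x (CAG - 35.5).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from patsy import build_design_matrices
from scipy import stats as sps

__all__ = [
    "dbs",
    "remove_outliers",
    "adequacy",
    "varimax",
    "pca_varimax",
    "PcaResult",
    "screen_covariates",
    "ancova",
    "AncovaResult",
    "simple_slopes",
    "spearman_family",
]


def dbs(age, cag):
    """Disease burden score: age x (CAG - 35.5)."""
    return np.asarray(age, dtype=float) * (np.asarray(cag, dtype=float) - 35.5)


# --------------------------------------------------------------------------
# Screening
# --------------------------------------------------------------------------

def remove_outliers(
    data: pd.DataFrame,
    value_col: str,
    group_col: str = "group",
    z_threshold: float = 3.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop values more than ``z_threshold`` SDs from their own group's mean.

    Returns the filtered frame and a removal log (row index, group, value,
    z-score). Each group needs at least 3 values.
    """
    logs = []
    keep = pd.Series(True, index=data.index)
    for g, sub in data.groupby(group_col):
        if len(sub) < 3:
            raise ValueError(f"group {g!r} has fewer than 3 values")
        mu, sd = sub[value_col].mean(), sub[value_col].std(ddof=1)
        if sd == 0:
            continue
        z = (sub[value_col] - mu) / sd
        bad = z.abs() > z_threshold
        keep.loc[sub.index[bad]] = False
        for i in sub.index[bad]:
            logs.append({"index": i, group_col: g,
                         "value": data.loc[i, value_col], "z": float(z.loc[i])})
    return data.loc[keep].copy(), pd.DataFrame(logs, columns=["index", group_col, "value", "z"])


def screen_covariates(
    outcome: pd.Series,
    candidates: pd.DataFrame,
    threshold: float = 0.3,
) -> list[str]:
    """Candidate covariates whose Pearson |r| with the outcome exceeds the
    moderate-relationship threshold (default 0.3)."""
    selected = []
    for name in candidates.columns:
        pair = pd.concat([outcome, candidates[name]], axis=1).dropna()
        r = np.corrcoef(pair.iloc[:, 0], pair.iloc[:, 1])[0, 1]
        if abs(r) > threshold:
            selected.append(name)
    return selected


# --------------------------------------------------------------------------
# PCA with adequacy tests and varimax
# --------------------------------------------------------------------------

def adequacy(X: pd.DataFrame | np.ndarray) -> dict:
    """Kaiser-Meyer-Olkin sampling adequacy and Bartlett's sphericity test.

    KMO compares zero-order with partial correlations; Bartlett tests
    R = I with chi^2 = -(n - 1 - (2p + 5)/6) ln det(R), df = p(p-1)/2.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if n <= p:
        raise ValueError("Bartlett's test needs more observations than variables")
    R = np.corrcoef(X, rowvar=False)
    sign, logdet = np.linalg.slogdet(R)
    if sign <= 0 or not np.isfinite(logdet) or np.linalg.cond(R) > 1e10:
        raise ValueError("singular correlation matrix")
    chi2 = -(n - 1 - (2 * p + 5) / 6.0) * logdet
    df = p * (p - 1) // 2
    p_value = float(sps.chi2.sf(chi2, df))

    Rinv = np.linalg.inv(R)
    d = np.sqrt(np.outer(np.diag(Rinv), np.diag(Rinv)))
    partial = -Rinv / d
    off = ~np.eye(p, dtype=bool)
    kmo = float(np.sum(R[off] ** 2) / (np.sum(R[off] ** 2) + np.sum(partial[off] ** 2)))
    return {"kmo": kmo, "bartlett_chi2": float(chi2), "bartlett_df": int(df),
            "bartlett_p": p_value}


def varimax(loadings: np.ndarray, normalize: bool = True,
            tol: float = 1e-10, max_iter: int = 1000) -> tuple[np.ndarray, np.ndarray]:
    """Orthogonal varimax rotation (Kaiser-normalized by default).

    Returns (rotated loadings, rotation matrix). A single column is
    returned unchanged with the identity rotation.
    """
    L = np.asarray(loadings, dtype=float).copy()
    p, k = L.shape
    if k < 2:
        return L, np.eye(k)
    h = np.sqrt(np.sum(L**2, axis=1)) if normalize else np.ones(p)
    h[h == 0] = 1.0
    L = L / h[:, None]
    R = np.eye(k)
    var_old = 0.0
    for _ in range(max_iter):
        Lam = L @ R
        grad = L.T @ (Lam**3 - Lam @ np.diag(np.sum(Lam**2, axis=0)) / p)
        U, S, Vt = np.linalg.svd(grad)
        R = U @ Vt
        var_new = float(np.sum(S))
        if var_new < var_old * (1 + tol):
            break
        var_old = var_new
    rotated = (L @ R) * h[:, None]
    return rotated, R


@dataclass
class PcaResult:
    eigenvalues: np.ndarray
    loadings_unrotated: np.ndarray      # (p, k) retained
    loadings: np.ndarray                # (p, k) varimax-rotated
    rotation: np.ndarray                # (k, k) orthogonal
    variance_explained: np.ndarray      # % of total variance, rotated
    scores: pd.DataFrame                # per-observation regression scores
    n_components: int
    component_labels: list[str] = field(default_factory=list)
    variable_names: list[str] = field(default_factory=list)
    adequacy: dict = field(default_factory=dict)


def pca_varimax(
    X: pd.DataFrame,
    retain: str | int = "kaiser",
    loading_threshold: float = 0.5,
    rotate: bool = True,
    check_adequacy: bool = True,
) -> PcaResult:
    """Correlation-matrix PCA with varimax rotation and regression scores.

    ``retain="kaiser"`` keeps components with eigenvalue > 1; an integer
    keeps a fixed count. Scores are computed by the regression method,
    ``Z R^{-1} Lambda``, on the rotated loadings (rotation is the identity
    when a single component is retained). Components are labeled by their
    dominant-|loading| variable.
    """
    if not isinstance(X, pd.DataFrame):
        X = pd.DataFrame(np.asarray(X, dtype=float))
    if X.isna().any().any():
        raise ValueError("PCA input must be complete (no missing values)")
    sds = X.std(ddof=1)
    zero = sds[sds == 0]
    if len(zero):
        raise ValueError(f"zero-variance column(s): {list(zero.index)}")
    Z = ((X - X.mean()) / sds).to_numpy()
    n, p = Z.shape
    R = np.corrcoef(Z, rowvar=False)
    eigval, eigvec = np.linalg.eigh(R)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]

    if retain == "kaiser":
        k = max(int(np.sum(eigval > 1.0)), 1)
    else:
        k = int(retain)
        if not 1 <= k <= p:
            raise ValueError(f"cannot retain {k} of {p} components")
    L_unrot = eigvec[:, :k] * np.sqrt(eigval[:k])
    if rotate and k >= 2:
        L_rot, rot = varimax(L_unrot)
    else:
        L_rot, rot = L_unrot.copy(), np.eye(k)

    # order rotated components by explained variance, sign so the dominant
    # loading is positive (rotation leaves both free)
    ss = np.sum(L_rot**2, axis=0)
    comp_order = np.argsort(ss)[::-1]
    L_rot = L_rot[:, comp_order]
    rot = rot[:, comp_order]
    signs = np.sign(L_rot[np.argmax(np.abs(L_rot), axis=0), np.arange(k)])
    signs[signs == 0] = 1.0
    L_rot = L_rot * signs
    rot = rot * signs
    var_pct = np.sum(L_rot**2, axis=0) / p * 100.0

    W = np.linalg.solve(R, L_rot)
    scores = pd.DataFrame(Z @ W, index=X.index,
                          columns=[f"PC{i + 1}" for i in range(k)])
    labels = [str(X.columns[int(np.argmax(np.abs(L_rot[:, j])))]) for j in range(k)]
    adq = adequacy(X) if check_adequacy and n > p else {}
    return PcaResult(
        eigenvalues=eigval, loadings_unrotated=L_unrot, loadings=L_rot,
        rotation=rot, variance_explained=var_pct, scores=scores,
        n_components=k, component_labels=labels,
        variable_names=[str(c) for c in X.columns], adequacy=adq,
    )


# --------------------------------------------------------------------------
# ANCOVA and moderation
# --------------------------------------------------------------------------

@dataclass
class AncovaResult:
    model: object                       # fitted statsmodels OLS results
    anova_table: pd.DataFrame           # Type III F table
    adjusted_means: pd.DataFrame
    formula: str
    dv: str = "score"
    data: pd.DataFrame = field(repr=False, default=None)


def ancova(
    data: pd.DataFrame,
    dv: str = "score",
    factors: tuple[str, ...] = ("group", "segment"),
    covariates: tuple[str, ...] = (),
    factor_interactions: tuple[tuple[str, str], ...] = (("group", "segment"),),
    covariate_interactions: tuple[tuple[str, str], ...] = (),
) -> AncovaResult:
    """OLS ANCOVA with sum-to-zero factor coding and Type III F tests.

    ``factor_interactions`` are factor x factor terms (e.g. group x segment);
    ``covariate_interactions`` are factor x covariate terms (e.g. group x
    age). Adjusted cell means are computed at the covariate means.
    """
    terms = [f"C({f}, Sum)" for f in factors]
    terms += list(covariates)
    terms += [f"C({a}, Sum):C({b}, Sum)" for a, b in factor_interactions]
    terms += [f"C({a}, Sum):{b}" for a, b in covariate_interactions]
    formula = f"{dv} ~ " + " + ".join(terms)
    model = smf.ols(formula, data=data).fit()
    if np.linalg.matrix_rank(model.model.exog) < model.model.exog.shape[1]:
        raise ValueError("rank-deficient design: aliased model terms")
    table = sm.stats.anova_lm(model, typ=3)
    table = table.rename(columns={"PR(>F)": "p", "F": "F"})

    cov_means = {c: float(data[c].mean()) for c in covariates}
    grid = data[[f for f in factors]].drop_duplicates().sort_values(list(factors))
    grid = grid.assign(**cov_means)
    grid["adjusted_mean"] = model.predict(grid)
    return AncovaResult(model=model, anova_table=table,
                        adjusted_means=grid.reset_index(drop=True),
                        formula=formula, dv=dv, data=data)


def simple_slopes(
    result: AncovaResult,
    moderator: str = "segment",
    effect: str = "group",
    effect_levels: tuple = ("patient", "control"),
) -> pd.DataFrame:
    """Conditional effect of ``effect`` at each level of ``moderator``.

    For every moderator level, the contrast patient-minus-control is
    evaluated with all covariates held at their means, giving the
    per-segment beta, SE, t and p implied by the fitted moderation model.
    Requires the effect x moderator interaction in the model.
    """
    if f"C({effect}, Sum):C({moderator}, Sum)" not in result.formula:
        raise ValueError(f"model lacks the {effect} x {moderator} interaction")
    data = result.data
    design_info = result.model.model.data.design_info
    cov_cols = [
        c for c in data.columns
        if c in result.formula and c not in (effect, moderator, result.dv)
        and pd.api.types.is_numeric_dtype(data[c])
    ]
    cov_means = {c: float(data[c].mean()) for c in cov_cols}
    rows = []
    for level in sorted(data[moderator].unique()):
        frames = []
        for ev in effect_levels:
            frames.append(pd.DataFrame({effect: [ev], moderator: [level], **{
                c: [m] for c, m in cov_means.items()}}))
        (X1,) = build_design_matrices([design_info], frames[0])
        (X0,) = build_design_matrices([design_info], frames[1])
        d = np.asarray(X1)[0] - np.asarray(X0)[0]
        beta = float(d @ result.model.params)
        se = float(np.sqrt(d @ result.model.cov_params() @ d))
        t = beta / se
        p = 2 * sps.t.sf(abs(t), result.model.df_resid)
        rows.append({moderator: level, "beta": beta, "se": se, "t": t, "p": p})
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Correlation families
# --------------------------------------------------------------------------

def _partial_pearson(x: np.ndarray, y: np.ndarray, Z: np.ndarray) -> tuple[float, float]:
    n = len(x)
    Z1 = np.column_stack([np.ones(n), Z])
    rx = x - Z1 @ np.linalg.lstsq(Z1, x, rcond=None)[0]
    ry = y - Z1 @ np.linalg.lstsq(Z1, y, rcond=None)[0]
    r = float(np.corrcoef(rx, ry)[0, 1])
    df = n - 2 - Z.shape[1]
    if df <= 0:
        raise ValueError("not enough observations for partial correlation")
    t = r * np.sqrt(df / max(1.0 - r**2, 1e-300))
    p = float(2 * sps.t.sf(abs(t), df))
    return r, p


def spearman_family(
    x: pd.DataFrame,
    y: pd.Series,
    covariates: pd.DataFrame | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Spearman correlations of ``y`` with each column of ``x`` (one per
    callosal segment), Bonferroni-corrected over the family.

    With covariates, the partial Spearman is the partial Pearson computed
    on rank-transformed data. Corrected p = min(1, m x raw p) with m the
    family size. Each pair needs >= 5 complete observations.
    """
    m = x.shape[1]
    rows = []
    for col in x.columns:
        cols = [x[col].rename("_x"), y.rename("_y")]
        if covariates is not None and covariates.shape[1] > 0:
            cols.append(covariates)
        frame = pd.concat(cols, axis=1).dropna()
        if len(frame) < 5:
            raise ValueError(f"fewer than 5 complete pairs for {col!r}")
        if frame["_x"].nunique() == 1 or frame["_y"].nunique() == 1:
            raise ValueError(f"constant input for {col!r}")
        if covariates is None or covariates.shape[1] == 0:
            r, p = sps.spearmanr(frame["_x"], frame["_y"])
        else:
            ranks = frame.rank()
            r, p = _partial_pearson(
                ranks["_x"].to_numpy(), ranks["_y"].to_numpy(),
                ranks.drop(columns=["_x", "_y"]).to_numpy(),
            )
        rows.append({
            "variable": col, "n": len(frame), "r": float(r), "p": float(p),
            "p_bonferroni": float(min(1.0, m * p)),
            "significant": bool(min(1.0, m * p) < alpha),
        })
    return pd.DataFrame(rows)
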