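"""Linear mixed models with a participant random intercept.

Each response (a gaze, head, questionnaire or heart-rate metric) is modeled
as

    y_ij = beta0 + beta' x_ij + b_i + e_ij,   b_i ~ N(0, tau^2),  e_ij ~ N(0, sigma^2)

with crossed categorical fixed effects (viewing condition, sex, and their
interaction by default) coded as 0/1 treatment dummies, and a random
intercept per participant. Estimation is REML via statsmodels' MixedLM.

Inference uses Wald t statistics with between-within denominator degrees of
freedom: terms that vary within participants are tested against
N − G − q_within degrees of freedom, purely between-participant terms against
G − q_between − 1 (N observations, G participants). In the balanced
two-condition, one-observation-per-cell case this reproduces the paired
t-test exactly.

Effect sizes are standardized betas (coefficient ÷ response SD, with 0/1
predictors), labeled small/medium/large around the conventional 0.2/0.5/0.8
anchors with boundaries at the midpoints 0.35 and 0.65. Post-hoc pairwise
comparisons of estimated marginal means use the studentized-range (Tukey)
adjustment; for a two-level factor the single contrast is identical to the
model coefficient test.
"""
from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from .errors import ModelError

__all__ = [
    "ModelSpec",
    "FixedEffectEstimate",
    "LmmFit",
    "fit_lmm",
    "standardized_beta",
    "effect_size_label",
    "tukey_posthoc",
]

#: |std beta| below 0.35 is "small", up to 0.65 "medium", above "large"
_LABEL_BOUNDS = (0.35, 0.65)


@dataclass(frozen=True)
class ModelSpec:
    """What to fit: response column, categorical fixed effects, grouping."""

    response: str
    fixed: tuple[str, ...] = ("condition", "sex")
    interaction: bool = True
    group: str = "participant_id"
    alpha: float = 0.05


@dataclass(frozen=True)
class FixedEffectEstimate:
    """One fixed-effect coefficient with CI, p and standardized effect size."""

    term: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    df: float
    p: float
    std_beta: float
    label: str


@dataclass
class LmmFit:
    """A fitted mixed model plus everything post-hoc tests need."""

    spec: ModelSpec
    estimates: list[FixedEffectEstimate]
    random_intercept_var: float
    resid_var: float
    converged: bool
    n_obs: int
    n_groups: int
    beta: np.ndarray = field(repr=False)
    cov_beta: np.ndarray = field(repr=False)
    columns: list[str] = field(repr=False)
    factor_levels: dict = field(repr=False)
    df_map: dict = field(repr=False)

    def estimate(self, term: str) -> FixedEffectEstimate:
        for e in self.estimates:
            if e.term == term:
                return e
        raise KeyError(term)

    def estimates_frame(self) -> pd.DataFrame:
        return pd.DataFrame([e.__dict__ for e in self.estimates])


def _design(data: pd.DataFrame, fixed: tuple[str, ...], interaction: bool):
    """0/1 treatment-coded design matrix with named columns and level maps."""
    n = len(data)
    cols = [np.ones(n)]
    names = ["Intercept"]
    levels: dict[str, list] = {}
    dummy_cols: dict[str, list[int]] = {}
    for f in fixed:
        lv = sorted(map(str, data[f].astype(str).unique()))
        if len(lv) < 2:
            raise ModelError(f"fixed factor {f!r} has fewer than 2 levels")
        levels[f] = lv
        dummy_cols[f] = []
        vals = data[f].astype(str).to_numpy()
        for level in lv[1:]:
            dummy_cols[f].append(len(cols))
            cols.append((vals == level).astype(float))
            names.append(f"{f}[{level}]")
    if interaction:
        if len(fixed) != 2:
            raise ModelError("interaction terms are supported for exactly two factors")
        f1, f2 = fixed
        for i in dummy_cols[f1]:
            for j in dummy_cols[f2]:
                cols.append(cols[i] * cols[j])
                names.append(f"{names[i]}:{names[j]}")
    return np.column_stack(cols), names, levels


def _denominator_dfs(X: np.ndarray, names: list[str], groups: np.ndarray) -> dict:
    """Between-within df per design column (and per kind, under keys
    '__within__'/'__between__')."""
    n, _ = X.shape
    ug, gidx = np.unique(groups, return_inverse=True)
    G = len(ug)
    within_col: dict[str, bool] = {}
    for k, name in enumerate(names):
        if name == "Intercept":
            within_col[name] = False
            continue
        col = X[:, k]
        varies = False
        for g in range(G):
            vals = col[gidx == g]
            if vals.size and (vals != vals[0]).any():
                varies = True
                break
        within_col[name] = varies
    q_within = sum(1 for nme, w in within_col.items() if w)
    q_between = sum(1 for nme, w in within_col.items() if not w and nme != "Intercept")
    df_within = max(n - G - q_within, 1)
    df_between = max(G - q_between - 1, 1)
    dfs = {nme: (df_within if w else df_between) for nme, w in within_col.items()}
    dfs["__within__"] = df_within
    dfs["__between__"] = df_between
    return dfs


def standardized_beta(beta: float, response_sd: float) -> float:
    """Coefficient in response-SD units (predictors 0/1 coded)."""
    if not response_sd > 0:
        raise ValueError("response_sd must be positive")
    return beta / response_sd


def effect_size_label(std_beta: float) -> str:
    """small / medium / large around the 0.2 / 0.5 / 0.8 anchors."""
    a = abs(std_beta)
    if a < _LABEL_BOUNDS[0]:
        return "small"
    if a < _LABEL_BOUNDS[1]:
        return "medium"
    return "large"


def fit_lmm(data: pd.DataFrame, spec: ModelSpec) -> LmmFit:
    """REML fit of the random-intercept model defined by ``spec``.

    Rows with a missing response are dropped listwise (mixed models tolerate
    the resulting unbalance). A singular fit (random-intercept variance
    estimated at the boundary) is reported with the variance floored at 0 and
    a warning, not an error; genuine non-convergence raises
    :class:`ModelError`.
    """
    needed = [spec.response, spec.group, *spec.fixed]
    missing = [c for c in needed if c not in data.columns]
    if missing:
        raise ModelError(f"model data missing column(s): {', '.join(missing)}")
    d = data.dropna(subset=[spec.response]).copy()
    y = d[spec.response].to_numpy(dtype=float)
    if not np.isfinite(y).all():
        raise ModelError(f"non-finite values in response {spec.response!r}")
    groups = d[spec.group].astype(str).to_numpy()
    cells = d.groupby([*spec.fixed], observed=True)[spec.group].nunique()
    if (cells < 2).any():
        raise ModelError("need at least 2 participants per design cell")

    X, names, levels = _design(d, spec.fixed, spec.interaction)
    # Fit on the SD-standardized response so responses of any unit (ms,
    # degrees, ms^-1) are equally well conditioned; rescale afterwards.
    sd_y = float(np.std(y, ddof=1))
    if not sd_y > 0:
        raise ModelError(f"response {spec.response!r} has zero variance")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", UserWarning)
        model = MixedLM(y / sd_y, X, groups=groups)
        res = None
        last_exc: Exception | None = None
        # L-BFGS is fastest but can step into a singular working covariance;
        # fall back to derivative-free optimizers when it does.
        for method in ("lbfgs", "powell", "cg", "nm"):
            try:
                cand = model.fit(reml=True, method=method)
            except Exception as exc:
                last_exc = exc
                continue
            if cand.converged:
                res = cand
                break
        if res is None:
            raise ModelError(f"mixed model failed to converge: {last_exc}")

    tau2 = float(np.asarray(res.cov_re)[0, 0]) * sd_y**2
    if tau2 < 1e-10:
        warnings.warn(
            f"singular fit for {spec.response!r}: random-intercept variance at boundary, floored at 0",
            RuntimeWarning,
            stacklevel=2,
        )
        tau2 = 0.0
    sigma2 = float(res.scale) * sd_y**2

    k = len(names)
    beta = np.asarray(res.fe_params, dtype=float) * sd_y
    cov_beta = np.asarray(res.cov_params())[:k, :k] * sd_y**2
    se = np.sqrt(np.diag(cov_beta))
    dfs = _denominator_dfs(X, names, groups)

    estimates = []
    for i, name in enumerate(names):
        df_i = dfs[name]
        t_i = beta[i] / se[i]
        p_i = 2.0 * stats.t.sf(abs(t_i), df_i)
        half = stats.t.ppf(0.975, df_i) * se[i]
        sb = standardized_beta(beta[i], sd_y) if name != "Intercept" else np.nan
        estimates.append(
            FixedEffectEstimate(
                term=name,
                beta=float(beta[i]),
                se=float(se[i]),
                ci_low=float(beta[i] - half),
                ci_high=float(beta[i] + half),
                df=float(df_i),
                p=float(p_i),
                std_beta=float(sb) if np.isfinite(sb) else float("nan"),
                label=effect_size_label(sb) if np.isfinite(sb) else "",
            )
        )

    return LmmFit(
        spec=spec,
        estimates=estimates,
        random_intercept_var=tau2,
        resid_var=sigma2,
        converged=bool(res.converged),
        n_obs=len(d),
        n_groups=int(len(np.unique(groups))),
        beta=beta,
        cov_beta=cov_beta,
        columns=names,
        factor_levels=levels,
        df_map=dfs,
    )


def _grid_row(fit: LmmFit, assignment: dict) -> np.ndarray:
    """Design row for one cell of the reference grid."""
    row = np.zeros(len(fit.columns))
    for i, name in enumerate(fit.columns):
        if name == "Intercept":
            row[i] = 1.0
            continue
        parts = name.split(":")
        val = 1.0
        for part in parts:
            f, level = part[:-1].split("[")
            val *= 1.0 if str(assignment[f]) == level else 0.0
        row[i] = val
    return row


def tukey_posthoc(fit: LmmFit, factor: str) -> pd.DataFrame:
    """Tukey-adjusted pairwise comparisons of estimated marginal means.

    Marginal means average model predictions over an equally weighted grid of
    the other fixed factors' levels. p-values use the studentized-range
    distribution with the factor's between-within denominator df.
    """
    if factor not in fit.factor_levels:
        raise ModelError(f"factor {factor!r} is not in the fitted model")
    levels = fit.factor_levels[factor]
    others = [f for f in fit.factor_levels if f != factor]
    other_grids = list(itertools.product(*[fit.factor_levels[f] for f in others])) or [()]

    emm_rows = {}
    for level in levels:
        rows = []
        for combo in other_grids:
            assignment = {factor: level, **dict(zip(others, combo))}
            rows.append(_grid_row(fit, assignment))
        emm_rows[level] = np.mean(rows, axis=0)

    df_err = fit.df_map.get(f"{factor}[{levels[1]}]", fit.df_map["__within__"])
    k = len(levels)
    out = []
    for a, b in itertools.combinations(levels, 2):
        c = emm_rows[b] - emm_rows[a]
        est = float(c @ fit.beta)
        se = float(np.sqrt(c @ fit.cov_beta @ c))
        q = abs(est) / se * np.sqrt(2.0)
        p = float(stats.studentized_range.sf(q, k, df_err))
        out.append(
            {
                "contrast": f"{b} - {a}",
                "estimate": est,
                "se": se,
                "df": float(df_err),
                "p_adj": p,
            }
        )
    return pd.DataFrame(out)


def holm_adjust(pvals) -> np.ndarray:
    """Holm step-down adjustment of a family of p-values."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj
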