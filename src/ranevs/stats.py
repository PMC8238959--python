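"""Group-level inference on per-participant condition summaries.

The design mirrors a cross-cultural case-control comparison: for each
response variable and each condition (symbolic / non-symbolic) a linear
model with fixed effects of diagnosis (ASD vs control), culture (HK vs US)
and their interaction, controlling for sex and age (plus IQ for the naming
performance variables).  When participants contribute repeated rows a
random-by-participant intercept is estimated (REML via statsmodels MixedLM);
with one row per participant the random intercept is unidentifiable and the
model reduces to ordinary least squares, which is fitted directly.

P-values across models are adjusted by Benjamini-Hochberg at FDR 0.10;
post-hoc cell contrasts use Tukey's studentized-range adjustment over the
four diagnosis x culture cells; skewed count outcomes (errors) fall back to
Mann-Whitney U tests; symptom correlates use partial Pearson correlations.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.api import MixedLM, OLS
from statsmodels.stats.multitest import multipletests

__all__ = ["EffectEstimate", "GroupModelResult", "ModelError",
           "fit_group_model", "bh_adjust", "pairwise_contrasts",
           "tukey_cell_contrasts", "mann_whitney", "partial_pearson",
           "chisq_counts", "NAMING_PERFORMANCE_RESPONSES"]


class ModelError(ValueError):
    """Model cannot be fitted (rank deficiency, missing factor levels...)."""


#: responses for which IQ joins the covariate set
NAMING_PERFORMANCE_RESPONSES = frozenset({"naming_time_s", "n_errors"})

_TERMS = ("culture", "diagnosis", "interaction")


@dataclass(frozen=True)
class EffectEstimate:
    term: str
    estimate: float
    se: float
    t: float
    p: float
    p_adj: Optional[float] = None


@dataclass
class GroupModelResult:
    """Fitted per-condition group model with everything contrasts need."""

    response: str
    condition: str
    effects: list[EffectEstimate]
    params: np.ndarray = field(repr=False)
    cov_params: np.ndarray = field(repr=False)
    column_names: list[str] = field(repr=False, default_factory=list)
    df_resid: float = np.nan
    n_obs: int = 0
    loglike_full: float = np.nan
    loglike_no_interaction: float = np.nan
    data: pd.DataFrame = field(repr=False, default=None)
    mixed: bool = False

    @property
    def lr_interaction(self) -> tuple[float, float]:
        """Likelihood-ratio statistic and p for dropping the interaction."""
        lr = 2.0 * (self.loglike_full - self.loglike_no_interaction)
        lr = max(lr, 0.0)
        return lr, float(sps.chi2.sf(lr, df=1))

    def effects_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{"term": e.term, "estimate": e.estimate, "se": e.se,
                              "t": e.t, "p": e.p, "p_adj": e.p_adj}
                             for e in self.effects])


def _design(df: pd.DataFrame, covariates: Sequence[str],
            with_interaction: bool = True) -> tuple[np.ndarray, list[str]]:
    """Treatment-coded design matrix; control and US are reference levels."""
    cols = {"const": np.ones(len(df))}
    cols["diagnosis[ASD]"] = (df["diagnosis"].astype(str) == "ASD").astype(float).to_numpy()
    cols["culture[HK]"] = (df["culture"].astype(str) == "HK").astype(float).to_numpy()
    if with_interaction:
        cols["diagnosis[ASD]:culture[HK]"] = cols["diagnosis[ASD]"] * cols["culture[HK]"]
    for c in covariates:
        v = df[c]
        if v.dtype == object or str(v.dtype) == "category":
            levels = sorted(v.astype(str).unique())
            for lev in levels[1:]:
                cols[f"{c}[{lev}]"] = (v.astype(str) == lev).astype(float).to_numpy()
        else:
            cols[c] = v.to_numpy(dtype=float)
    names = list(cols)
    X = np.column_stack([cols[k] for k in names])
    return X, names


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    r = np.linalg.matrix_rank(X)
    if r == X.shape[1]:
        return
    # walk the columns to name the first one aliased with its predecessors
    for j in range(1, X.shape[1]):
        if np.linalg.matrix_rank(X[:, : j + 1]) == np.linalg.matrix_rank(X[:, :j]):
            raise ModelError(f"design is rank deficient: term {names[j]!r} "
                             "is aliased with earlier terms")
    raise ModelError("design is rank deficient")


def fit_group_model(table: pd.DataFrame, response: str, condition: str,
                    covariates: Optional[Sequence[str]] = None) -> GroupModelResult:
    """Fit the diagnosis x culture model for one response in one condition.

    ``table`` holds one row per participant (x condition) with ``diagnosis``
    (ASD/control), ``culture`` (HK/US), the covariates and the response.
    ``covariates`` defaults to sex and age, plus IQ when the response is a
    naming performance variable.  Returns effect estimates for culture,
    diagnosis and their interaction; ``p_adj`` is left for a later
    :func:`bh_adjust` across the model family.
    """
    if covariates is None:
        covariates = ["sex", "age"]
        if response in NAMING_PERFORMANCE_RESPONSES:
            covariates = covariates + ["iq"]
    df = table[table["condition"].astype(str) == str(condition)].copy()
    need = ["participant_id", "diagnosis", "culture", response, *covariates]
    df = df.dropna(subset=[c for c in need if c in df.columns])
    if df.empty:
        raise ModelError(f"no rows for condition {condition!r}")
    for fac in ("diagnosis", "culture"):
        if df[fac].astype(str).nunique() < 2:
            raise ModelError(f"factor {fac!r} has fewer than 2 levels in the data")
    y = df[response].to_numpy(dtype=float)
    X_full, names = _design(df, covariates, with_interaction=True)
    X_red, _ = _design(df, covariates, with_interaction=False)
    if np.allclose(np.var(y), 0.0):
        # degenerate response: all effects are exactly zero
        effects = [EffectEstimate(t_, 0.0, 0.0, np.nan, 1.0) for t_ in _TERMS]
        return GroupModelResult(response=response, condition=str(condition),
                                effects=effects, params=np.zeros(X_full.shape[1]),
                                cov_params=np.zeros((X_full.shape[1],) * 2),
                                column_names=names, df_resid=len(df) - X_full.shape[1],
                                n_obs=len(df), loglike_full=np.nan,
                                loglike_no_interaction=np.nan, data=df, mixed=False)
    _check_rank(X_full, names)

    repeated = bool(df.duplicated(subset=["participant_id"]).any())
    term_cols = {"culture": names.index("culture[HK]"),
                 "diagnosis": names.index("diagnosis[ASD]"),
                 "interaction": names.index("diagnosis[ASD]:culture[HK]")}

    if repeated:
        groups = df["participant_id"].to_numpy()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = MixedLM(y, X_full, groups=groups).fit(reml=False)
            res_red = MixedLM(y, X_red, groups=groups).fit(reml=False)
        params = np.asarray(res.fe_params)
        cov = np.asarray(res.cov_params())[: len(names), : len(names)]
        # residual-df approximation for the t reference distribution
        df_resid = len(df) - X_full.shape[1]
        ll_full, ll_red = float(res.llf), float(res_red.llf)
    else:
        res = OLS(y, X_full).fit()
        res_red = OLS(y, X_red).fit()
        params = np.asarray(res.params)
        cov = np.asarray(res.cov_params())
        df_resid = float(res.df_resid)
        ll_full, ll_red = float(res.llf), float(res_red.llf)

    effects = []
    for term, j in [("culture", term_cols["culture"]),
                    ("diagnosis", term_cols["diagnosis"]),
                    ("interaction", term_cols["interaction"])]:
        est = float(params[j])
        se = float(np.sqrt(cov[j, j]))
        tval = est / se if se > 0 else np.nan
        p = float(2.0 * sps.t.sf(abs(tval), df_resid)) if np.isfinite(tval) else 1.0
        effects.append(EffectEstimate(term, est, se, tval, p))

    return GroupModelResult(
        response=response, condition=str(condition), effects=effects,
        params=params, cov_params=cov, column_names=names,
        df_resid=df_resid, n_obs=len(df), loglike_full=ll_full,
        loglike_no_interaction=ll_red, data=df, mixed=repeated)


def bh_adjust(p_values: Sequence[float], fdr_level: float = 0.10) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (FDR control).

    ``fdr_level`` is the nominal FDR used when thresholding the adjusted
    values; the adjusted values themselves do not depend on it.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, alpha=fdr_level, method="fdr_bh")[1]


@dataclass(frozen=True)
class CellContrast:
    cell_a: str
    cell_b: str
    estimate: float
    se: float
    t: float
    p_tukey: float


def tukey_cell_contrasts(means: dict, ses: dict, df_resid: float,
                         cov: Optional[dict] = None) -> list[CellContrast]:
    """All pairwise mean differences with studentized-range (Tukey) p-values.

    ``means``/``ses`` map cell label -> estimate / standard error; ``cov``
    optionally maps frozenset({a, b}) -> covariance of the two estimates.
    With two cells this reduces to a two-sided t-test.
    """
    labels = list(means)
    k = len(labels)
    out = []
    for a, b in itertools.combinations(labels, 2):
        diff = means[a] - means[b]
        c = cov.get(frozenset((a, b)), 0.0) if cov else 0.0
        se = float(np.sqrt(ses[a] ** 2 + ses[b] ** 2 - 2 * c))
        if se == 0:
            tval, p = np.nan, 1.0
        else:
            tval = diff / se
            q = abs(tval) * np.sqrt(2.0)
            p = float(sps.studentized_range.sf(q, k, df_resid))
        out.append(CellContrast(a, b, float(diff), se, tval, min(p, 1.0)))
    return out


def pairwise_contrasts(result: GroupModelResult,
                       factor_pair: tuple[str, str] = ("diagnosis", "culture")
                       ) -> list[CellContrast]:
    """Estimated-marginal-mean contrasts between the diagnosis x culture cells.

    Cell means are model predictions at the sample-mean covariate values
    (covariates cancel in the differences); the family-wise adjustment is
    Tukey's studentized range over the cells present.
    """
    df = result.data
    names = result.column_names
    lv_a = sorted(df[factor_pair[0]].astype(str).unique())
    lv_b = sorted(df[factor_pair[1]].astype(str).unique())
    cells = [(a, b) for a in lv_a for b in lv_b]

    # linear combination vector for each cell at mean covariates
    means, ses, covs = {}, {}, {}
    vecs = {}
    for (a, b) in cells:
        L = np.zeros(len(names))
        L[names.index("const")] = 1.0
        if "diagnosis[ASD]" in names:
            L[names.index("diagnosis[ASD]")] = float(a == "ASD")
        if "culture[HK]" in names:
            L[names.index("culture[HK]")] = float(b == "HK")
        if "diagnosis[ASD]:culture[HK]" in names:
            L[names.index("diagnosis[ASD]:culture[HK]")] = float(a == "ASD") * float(b == "HK")
        for j, nm in enumerate(names):
            if nm not in ("const", "diagnosis[ASD]", "culture[HK]",
                          "diagnosis[ASD]:culture[HK]"):
                col = nm.split("[")[0]
                if "[" in nm:  # categorical covariate dummy: use its sample mean
                    lev = nm[nm.index("[") + 1:-1]
                    L[j] = float(np.mean(df[col].astype(str) == lev))
                else:
                    L[j] = float(np.mean(df[col].to_numpy(dtype=float)))
        label = f"{a}-{b}"
        vecs[label] = L
        means[label] = float(L @ result.params)
        ses[label] = float(np.sqrt(L @ result.cov_params @ L))
    for la, lb in itertools.combinations(vecs, 2):
        covs[frozenset((la, lb))] = float(vecs[la] @ result.cov_params @ vecs[lb])
    return tukey_cell_contrasts(means, ses, result.df_resid, covs)


# ---------------------------------------------------------------------------
# Non-parametric and auxiliary tests
# ---------------------------------------------------------------------------

def mann_whitney(x: Sequence[float], y: Sequence[float],
                 exact_max_n: int = 12) -> tuple[float, float]:
    """Mann-Whitney U test (two-sided).

    Returns ``(U1, p)`` where U1 counts (x > y) pairs plus half the ties.
    When ``n1 + n2 <= exact_max_n`` the p-value is computed by exhaustive
    enumeration of all group assignments of the pooled values (valid with
    ties); otherwise a tie-corrected normal approximation with continuity
    correction is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = x.size, y.size
    if n1 == 0 or n2 == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    U1 = float(np.sum(ranks[:n1]) - n1 * (n1 + 1) / 2.0)
    mu = n1 * n2 / 2.0

    if n1 + n2 <= exact_max_n:
        # exact null distribution of U over all C(n, n1) assignments
        idx_all = range(n1 + n2)
        dev = abs(U1 - mu)
        hits = total = 0
        for combo in itertools.combinations(idx_all, n1):
            u = float(np.sum(ranks[list(combo)]) - n1 * (n1 + 1) / 2.0)
            total += 1
            if abs(u - mu) >= dev - 1e-12:
                hits += 1
        return U1, hits / total

    # tie-corrected normal approximation
    n = n1 + n2
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts ** 3 - counts)) / (n * (n - 1))
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if sigma2 <= 0:
        return U1, 1.0
    z = (abs(U1 - mu) - 0.5) / np.sqrt(sigma2)
    return U1, float(2.0 * sps.norm.sf(max(z, 0.0)))


def partial_pearson(x: Sequence[float], y: Sequence[float],
                    covariates: Optional[np.ndarray] = None) -> tuple[float, float]:
    """Partial Pearson correlation of x and y given linear covariates.

    Both variables are residualised on ``covariates`` (n x k, or None) plus
    an intercept; the correlation of the residuals is returned with a
    two-sided p from the t transform on ``n - 2 - k`` degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if covariates is None:
        Z = np.ones((n, 1))
        k = 0
    else:
        Z = np.atleast_2d(np.asarray(covariates, dtype=float))
        if Z.shape[0] != n:
            Z = Z.T
        k = Z.shape[1]
        Z = np.column_stack([np.ones(n), Z])
    if n < k + 3:
        raise ValueError(f"need at least {k + 3} complete cases, got {n}")
    rx = x - Z @ np.linalg.lstsq(Z, x, rcond=None)[0]
    ry = y - Z @ np.linalg.lstsq(Z, y, rcond=None)[0]
    sx, sy = np.std(rx), np.std(ry)
    if sx == 0 or sy == 0:
        raise ValueError("degenerate (zero-variance) residuals; correlation undefined")
    r = float(np.clip(np.dot(rx, ry) / (n * sx * sy), -1.0, 1.0))
    dof = n - 2 - k
    if abs(r) == 1.0:
        return r, 0.0
    tval = r * np.sqrt(dof / (1.0 - r * r))
    return r, float(2.0 * sps.t.sf(abs(tval), dof))


def chisq_counts(contingency) -> tuple[float, int, float]:
    """Pearson chi-squared on a contingency table (no continuity correction)."""
    obs = np.asarray(contingency, dtype=float)
    if np.any(obs < 0) or not np.allclose(obs, np.round(obs)):
        raise ValueError("contingency table must hold non-negative integer counts")
    if np.any(obs.sum(axis=0) == 0) or np.any(obs.sum(axis=1) == 0):
        raise ValueError("contingency table has a zero marginal")
    res = sps.chi2_contingency(obs, correction=False)
    return float(res.statistic), int(res.dof), float(res.pvalue)
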