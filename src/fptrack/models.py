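"""Random-intercept model selection for mean first-passage time.

The response is the natural log of each polygon's mFPT_Rmax.  Thirty-six
candidate linear mixed models — singles, current-condition ("reactive")
combinations, and 16/32-day lag-difference ("prescient") combinations, all
with a random intercept per bird — are fitted by maximum likelihood and
ranked by the small-sample corrected information criterion AICc.  ML rather
than REML is used throughout so that likelihoods are comparable across
different fixed-effect structures.

Diagnostics mirror standard mixed-model practice: marginal/conditional
R² (variance explained by fixed effects alone vs. fixed plus random),
variance inflation factors and the design-matrix condition number for
collinearity, and an empirical semivariogram of residuals against distance
for spatial autocorrelation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

logger = logging.getLogger("fptrack")

NUMERIC_PREDICTORS = [
    "ndvi_t",
    "d_ndvi_16",
    "d_ndvi_32",
    "mndwi_t",
    "d_mndwi_16",
    "d_mndwi_32",
    "precip_t",
    "d_precip_16",
    "d_precip_32",
    "temp",
    "elev",
]


@dataclass(frozen=True)
class ModelSpec:
    """One candidate model: fixed terms plus a random intercept per bird."""

    model_id: int
    terms: tuple[str, ...]  # subset of NUMERIC_PREDICTORS + {"site"}
    hypothesis: str  # single | RM | PM16 | PM32 | null

    def formula(self, response: str = "log_mfpt") -> str:
        rhs = " + ".join(self.terms) if self.terms else "1"
        return f"{response} ~ {rhs}"

    def label(self) -> str:
        rhs = " + ".join(self.terms) if self.terms else "1"
        return f"mFPT_Rmax ~ {rhs} + (1|ID)"


@dataclass
class FitResult:
    """A fitted candidate with ML likelihood, AICc inputs and diagnostics."""

    model_id: int
    spec: ModelSpec
    params: pd.Series
    bse: pd.Series
    conf_int: pd.DataFrame
    sigma2_id: float
    sigma2_resid: float
    loglik: float
    n_obs: int
    k: int
    aicc: float
    r2_marginal: float
    r2_conditional: float
    fitted_fixed: np.ndarray = field(repr=False, default=None)
    residuals: np.ndarray = field(repr=False, default=None)
    boundary_fit: bool = False
    converged: bool = True


@dataclass
class Semivariogram:
    """Empirical semivariance of residuals by distance bin."""

    bin_edges: np.ndarray
    pair_counts: np.ndarray
    gamma: np.ndarray


def prepare_inputs(
    table: pd.DataFrame,
    outlier_z: float = 3.0,
    reference_site: str | None = None,
) -> pd.DataFrame:
    """Log-transform the response, drop outliers, and z-score predictors.

    Records whose log response lies more than ``outlier_z`` standard
    deviations from the mean are removed (logged); each numeric predictor is
    then standardised to mean 0, s.d. 1 over the retained records.  ``site``
    is recoded as an ordered categorical whose first level is the reference
    (default: alphabetical first).
    """
    if table.empty:
        raise ValueError("empty covariate table")
    df = table.copy()
    if "log_mfpt" not in df:
        df["log_mfpt"] = np.log(df["mfpt_rmax_h"])
    z = (df["log_mfpt"] - df["log_mfpt"].mean()) / df["log_mfpt"].std(ddof=1)
    keep = z.abs() <= outlier_z
    if (~keep).any():
        logger.info("prepare_inputs: removed %d response outliers (|z| > %g)", int((~keep).sum()), outlier_z)
    df = df.loc[keep].reset_index(drop=True)
    for col in NUMERIC_PREDICTORS:
        if col not in df:
            continue
        sd = df[col].std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            raise ValueError(f"predictor {col!r} has zero variance")
        df[col] = (df[col] - df[col].mean()) / sd
    if "site" in df:
        levels = sorted(df["site"].unique())
        if reference_site is not None:
            if reference_site not in levels:
                raise ValueError(f"reference site {reference_site!r} not among {levels}")
            levels = [reference_site] + [s for s in levels if s != reference_site]
        df["site"] = pd.Categorical(df["site"], categories=levels)
    return df


def candidate_set() -> list[ModelSpec]:
    """The 36 candidate models.

    1–9 are single environmental terms (current value and 16/32-day change
    of NDVI, mNDWI and precipitation), 10 site, 11 temperature + elevation;
    12–15 current-condition combinations (reactive hypothesis) and 16–19 the
    same plus site, temperature and elevation; 20–27 the 16-day lag
    combinations (prescient) without/with site; 28–35 the 32-day analogues;
    36 the intercept-only null.  Every model carries the per-bird random
    intercept.
    """
    specs: list[ModelSpec] = []
    singles = [
        ("ndvi_t",),
        ("d_ndvi_16",),
        ("d_ndvi_32",),
        ("mndwi_t",),
        ("d_mndwi_16",),
        ("d_mndwi_32",),
        ("precip_t",),
        ("d_precip_16",),
        ("d_precip_32",),
        ("site",),
        ("temp", "elev"),
    ]
    for i, terms in enumerate(singles, start=1):
        specs.append(ModelSpec(i, terms, "single"))
    rm_base = [
        ("ndvi_t", "mndwi_t", "precip_t"),
        ("ndvi_t", "mndwi_t"),
        ("ndvi_t", "precip_t"),
        ("mndwi_t", "precip_t"),
    ]
    for i, terms in enumerate(rm_base, start=12):
        specs.append(ModelSpec(i, terms, "RM"))
    for i, terms in enumerate(rm_base, start=16):
        specs.append(ModelSpec(i, terms + ("site", "temp", "elev"), "RM"))
    pm16 = [
        ("d_ndvi_16", "d_mndwi_16", "d_precip_16"),
        ("d_ndvi_16", "d_mndwi_16"),
        ("d_ndvi_16", "d_precip_16"),
        ("d_mndwi_16", "d_precip_16"),
    ]
    for i, terms in enumerate(pm16, start=20):
        specs.append(ModelSpec(i, terms, "PM16"))
    for i, terms in enumerate(pm16, start=24):
        specs.append(ModelSpec(i, terms + ("site",), "PM16"))
    pm32 = [
        ("d_ndvi_32", "d_mndwi_32", "d_precip_32"),
        ("d_ndvi_32", "d_mndwi_32"),
        ("d_ndvi_32", "d_precip_32"),
        ("d_mndwi_32", "d_precip_32"),
    ]
    for i, terms in enumerate(pm32, start=28):
        specs.append(ModelSpec(i, terms, "PM32"))
    for i, terms in enumerate(pm32, start=32):
        specs.append(ModelSpec(i, terms + ("site",), "PM32"))
    specs.append(ModelSpec(36, (), "null"))
    return specs


def aicc(loglik: float, k: int, n: int) -> float:
    """Small-sample corrected AIC: −2·logL + 2k + 2k(k+1)/(n − k − 1)."""
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n}, k={k} (needs n > k + 1)")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def _design_matrix(spec: ModelSpec, data: pd.DataFrame) -> pd.DataFrame:
    """Fixed-effects design matrix (with intercept) for a spec."""
    import patsy  # statsmodels dependency

    return patsy.dmatrix(
        " + ".join(spec.terms) if spec.terms else "1", data, return_type="dataframe"
    )


def fit_mixed_model(spec: ModelSpec, data: pd.DataFrame, response: str = "log_mfpt") -> FitResult:
    """Fit one candidate by ML with a random intercept per ``bird_id``.

    Singular fits (between-bird variance on the zero boundary) are returned
    with ``boundary_fit=True`` rather than raising.
    """
    if data["bird_id"].nunique() < 2:
        raise ValueError("need >= 2 random-effect groups")
    formula = spec.formula(response)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(formula, data, groups=data["bird_id"])
        res = None
        for method in ("lbfgs", None, "powell", "cg"):
            try:
                kwargs = {} if method is None else {"method": method}
                cand = model.fit(reml=False, **kwargs)
            except Exception:
                continue
            if np.isfinite(cand.llf) and np.all(np.isfinite(np.asarray(cand.params))):
                res = cand
                break
        if res is None:
            raise RuntimeError(f"model {spec.model_id}: no optimizer produced a finite fit")
    sigma2_id = float(np.asarray(res.cov_re).ravel()[0]) if res.cov_re.size else 0.0
    sigma2_resid = float(res.scale)
    boundary = sigma2_id < 1e-8 * max(sigma2_resid, 1e-12)
    fe_names = [n for n in res.params.index if n != "Group Var"]
    params = res.params[fe_names]
    bse = res.bse[fe_names]
    ci = res.conf_int().loc[fe_names]
    ci.columns = ["lower", "upper"]
    X = _design_matrix(spec, data)
    fitted_fixed = X.to_numpy() @ params.reindex(X.columns).to_numpy()
    y = data[response].to_numpy(dtype=float)
    try:
        resid = y - np.asarray(res.fittedvalues)
    except Exception:  # singular random-effect covariance: fixed-only residuals
        resid = y - fitted_fixed
    k = len(fe_names) + 2  # fixed effects (incl. intercept) + two variance components
    n = len(data)
    var_f = float(np.var(fitted_fixed, ddof=1)) if n > 1 else 0.0
    denom = var_f + sigma2_id + sigma2_resid
    if denom <= 0:
        raise ValueError("all variance components zero; R2 undefined")
    return FitResult(
        model_id=spec.model_id,
        spec=spec,
        params=params,
        bse=bse,
        conf_int=ci,
        sigma2_id=sigma2_id,
        sigma2_resid=sigma2_resid,
        loglik=float(res.llf),
        n_obs=n,
        k=k,
        aicc=aicc(float(res.llf), k, n),
        r2_marginal=var_f / denom,
        r2_conditional=(var_f + sigma2_id) / denom,
        fitted_fixed=fitted_fixed,
        residuals=resid,
        boundary_fit=bool(boundary),
        converged=bool(res.converged),
    )


def r2_glmm(fit: FitResult) -> tuple[float, float]:
    """Marginal and conditional R²: fixed-effect variance share vs. fixed
    plus random, over the total of fixed + between-bird + residual."""
    return fit.r2_marginal, fit.r2_conditional


def rank_models(fits: list[FitResult]) -> pd.DataFrame:
    """AICc selection table: ΔAICc, Akaike weights, cumulative weight.

    All fits must use identical data rows; ties in AICc are ordered by
    smaller k then model_id.
    """
    ns = {f.n_obs for f in fits}
    if len(ns) != 1:
        raise ValueError(f"fits use differing n_obs: {sorted(ns)}")
    rows = pd.DataFrame(
        {
            "model_id": [f.model_id for f in fits],
            "formula": [f.spec.label() for f in fits],
            "hypothesis": [f.spec.hypothesis for f in fits],
            "K": [f.k for f in fits],
            "AICc": [f.aicc for f in fits],
        }
    )
    rows = rows.sort_values(["AICc", "K", "model_id"], kind="mergesort").reset_index(drop=True)
    rows["dAICc"] = rows["AICc"] - rows["AICc"].iloc[0]
    w = np.exp(-0.5 * rows["dAICc"].to_numpy())
    rows["weight"] = w / w.sum()
    rows["cum_weight"] = rows["weight"].cumsum()
    return rows


def collinearity_diagnostics(X: pd.DataFrame) -> tuple[float, pd.Series]:
    """Condition number (kappa) and VIF per term of a design matrix.

    ``X`` holds the non-intercept columns.  Columns are standardised before
    the singular-value decomposition; VIFs come from regressing each column
    on the others (categorical terms passed as their dummy block yield a
    generalised VIF via the determinant formula).  Exactly collinear columns
    give ``kappa = inf``.
    """
    if X.shape[1] < 2:
        raise ValueError("need >= 2 columns beyond the intercept")
    Z = (X - X.mean()) / X.std(ddof=1)
    if Z.isna().any().any():
        raise ValueError("zero-variance column in design matrix")
    s = np.linalg.svd(Z.to_numpy(), compute_uv=False)
    kappa = float(s[0] / s[-1]) if s[-1] > 1e-12 * s[0] else float("inf")
    corr = np.corrcoef(Z.to_numpy(), rowvar=False)
    vifs = {}
    try:
        inv = np.linalg.inv(corr)
        for j, name in enumerate(X.columns):
            vifs[name] = float(inv[j, j])
    except np.linalg.LinAlgError:
        for name in X.columns:
            vifs[name] = float("inf")
    return kappa, pd.Series(vifs)


def generalized_vif(X: pd.DataFrame, groups: dict[str, list[str]]) -> pd.Series:
    """GVIF per term where ``groups`` maps term -> its design columns
    (dummy blocks for categorical terms); det(R11)·det(R22)/det(R)."""
    Z = (X - X.mean()) / X.std(ddof=1)
    R = np.corrcoef(Z.to_numpy(), rowvar=False)
    cols = list(X.columns)
    out = {}
    detR = np.linalg.det(R)
    for term, members in groups.items():
        idx = [cols.index(m) for m in members]
        rest = [i for i in range(len(cols)) if i not in idx]
        r11 = np.linalg.det(R[np.ix_(idx, idx)])
        r22 = np.linalg.det(R[np.ix_(rest, rest)]) if rest else 1.0
        out[term] = float(r11 * r22 / detR) if detR > 1e-300 else float("inf")
    return pd.Series(out)


def residual_semivariogram(
    residuals: np.ndarray, centroids: np.ndarray, n_bins: int = 12
) -> Semivariogram:
    """Empirical semivariogram γ(h) of residuals over equal-width distance
    bins up to the maximum pairwise distance."""
    r = np.asarray(residuals, dtype=float)
    c = np.asarray(centroids, dtype=float)
    if len(r) < 2:
        raise ValueError("semivariogram needs >= 2 points")
    if len(r) < 10:
        logger.warning("semivariogram on only %d points", len(r))
    from scipy.spatial.distance import pdist

    d = pdist(c)
    dr2 = pdist(r[:, None], metric="sqeuclidean")
    edges = np.linspace(0.0, d.max(), n_bins + 1)
    which = np.clip(np.digitize(d, edges[1:-1]), 0, n_bins - 1)
    counts = np.bincount(which, minlength=n_bins)
    sums = np.bincount(which, weights=dr2, minlength=n_bins)
    with np.errstate(invalid="ignore", divide="ignore"):
        gamma = np.where(counts > 0, sums / (2.0 * np.maximum(counts, 1)), np.nan)
    return Semivariogram(bin_edges=edges, pair_counts=counts, gamma=gamma)


def fit_candidates(
    data: pd.DataFrame, specs: list[ModelSpec] | None = None, response: str = "log_mfpt"
) -> list[FitResult]:
    """Fit the full candidate set on one prepared table."""
    specs = candidate_set() if specs is None else specs
    fits = []
    for spec in specs:
        try:
            fits.append(fit_mixed_model(spec, data, response=response))
        except Exception as err:  # pragma: no cover - survives pathological tables
            logger.warning("model %d failed to fit: %s", spec.model_id, err)
    return fits
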