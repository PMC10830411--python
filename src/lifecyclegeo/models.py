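"""Driver models of annual proportion.

This module fits and compares the regression models that link regional
annual-herb proportions to climate and disturbance:

* the *yearly model* — proportion ~ bio1 * bio12 (mean annual temperature,
  total annual precipitation, and their interaction);
* the *quarterly search* — an exhaustive AICc comparison of 34 two-feature
  models pairing one quarterly temperature variable (bio8-bio11) with one
  quarterly precipitation variable (bio16-bio19, raw or log(x+1)), plus
  the two yearly baselines (bio1 with bio12 or log(bio12+1));
* nested extensions adding interannual variability (ipv, itv) and human
  footprint;
* per-family refits of the selected model;
* alternative response formulations (logit-transformed proportions and a
  Poisson GLM with a log-total offset);
* distance-based Moran eigenvector maps (dbMEM) to absorb spatial
  autocorrelation;
* phylogenetic generalized least squares (pGLS) under Brownian motion at
  the species level;
* sampling-bias diagnostics against GBIF observation depth.

Model terms are expressed in a tiny grammar: a bare column name, a
log-transform ``log(col+1)`` (natural log), or an interaction ``a:b`` of
two such terms. An intercept is always included.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.sparse.csgraph import minimum_spanning_tree

from ._geometry import haversine_matrix

QUARTER_TEMP_VARS = ("bio8", "bio9", "bio10", "bio11")
QUARTER_PREC_VARS = ("bio16", "bio17", "bio18", "bio19")


# --- term grammar -----------------------------------------------------------

def _eval_atom(term: str, table: pd.DataFrame) -> pd.Series:
    m = re.fullmatch(r"log\((\w+)\+1\)", term)
    if m:
        return np.log(table[m.group(1)] + 1.0)
    return table[term]


def eval_term(term: str, table: pd.DataFrame) -> pd.Series:
    """Evaluate one model term against a table of predictors."""
    if ":" in term:
        a, b = term.split(":", 1)
        return _eval_atom(a, table) * _eval_atom(b, table)
    return _eval_atom(term, table)


def term_columns(term: str) -> set[str]:
    """Raw table columns a term depends on."""
    cols = set()
    for part in term.split(":"):
        m = re.fullmatch(r"log\((\w+)\+1\)", part)
        cols.add(m.group(1) if m else part)
    return cols


@dataclass(frozen=True)
class ModelSpec:
    """A response column, predictor terms, and a family."""

    response: str
    predictors: tuple[str, ...]
    family: str = "gaussian-ols"  # gaussian-ols | poisson-log-offset | pgls-brownian

    def __post_init__(self) -> None:
        if len(set(self.predictors)) != len(self.predictors):
            raise ValueError("predictor terms must be distinct")

    def columns(self) -> set[str]:
        cols = {self.response}
        for t in self.predictors:
            cols |= term_columns(t)
        return cols


@dataclass
class ModelFit:
    """Coefficients and fit summaries of one fitted model.

    AICc counts the residual variance as an estimated parameter:
    k = (number of mean parameters) + 1 and AICc = AIC + 2k(k+1)/(n-k-1).
    """

    spec: ModelSpec
    params: dict[str, float]
    bse: dict[str, float]
    pvalues: dict[str, float]
    r2: float | None
    loglik: float
    aic: float
    aicc: float
    n: int
    df_resid: int
    extra: dict = field(default_factory=dict)

    def predict(self, table: pd.DataFrame) -> pd.Series:
        """Linear predictor (response scale for gaussian fits)."""
        out = pd.Series(self.params["const"], index=table.index, dtype=float)
        for term in self.spec.predictors:
            out = out + self.params[term] * eval_term(term, table)
        return out

    def to_dict(self) -> dict:
        return {
            "response": self.spec.response,
            "predictors": list(self.spec.predictors),
            "family": self.spec.family,
            "params": self.params,
            "bse": self.bse,
            "r2": self.r2,
            "aicc": self.aicc,
            "n": self.n,
        }


def _aicc_from_llf(llf: float, n: int, k: int) -> float:
    aic = -2.0 * llf + 2.0 * k
    if n - k - 1 <= 0:
        return np.inf
    return aic + 2.0 * k * (k + 1) / (n - k - 1)


def _design(spec: ModelSpec, table: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame]:
    cols = spec.columns()
    missing = cols - set(table.columns)
    if missing:
        raise KeyError(f"table lacks columns {sorted(missing)}")
    cc = table.dropna(subset=sorted(cols))
    X = pd.DataFrame({"const": 1.0, **{t: eval_term(t, cc) for t in spec.predictors}}, index=cc.index)
    y = cc[spec.response].astype(float)
    return X, y, cc


def fit_linear(spec: ModelSpec, table: pd.DataFrame) -> ModelFit:
    """Ordinary least squares on complete cases.

    Raises on a rank-deficient design, naming the collinear columns.
    """
    X, y, _ = _design(spec, table)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # identify offending columns by greedy rank growth
        bad = []
        keep: list[str] = []
        for col in X.columns:
            trial = keep + [col]
            if np.linalg.matrix_rank(X[trial].to_numpy()) == len(keep):
                bad.append(col)
            else:
                keep = trial
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")
    res = sm.OLS(y, X).fit()
    k = X.shape[1] + 1
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = float(res.rsquared)  # undefined for a constant response
    return ModelFit(
        spec=spec,
        params=dict(res.params),
        bse=dict(res.bse),
        pvalues=dict(res.pvalues),
        r2=r2 if np.isfinite(r2) else np.nan,
        loglik=float(res.llf),
        aic=-2.0 * res.llf + 2.0 * k,
        aicc=_aicc_from_llf(res.llf, int(res.nobs), k),
        n=int(res.nobs),
        df_resid=int(res.df_resid),
    )


def yearly_model(table: pd.DataFrame, response: str = "p_annual_herb") -> ModelFit:
    """The yearly headline model: response ~ bio1 + bio12 + bio1:bio12."""
    return fit_linear(ModelSpec(response, ("bio1", "bio12", "bio1:bio12")), table)


# --- exhaustive quarterly search -------------------------------------------

@dataclass
class SearchResult:
    """AICc ranking of the exhaustive quarterly model search."""

    fits: list[ModelFit]  # sorted by AICc, best first
    ranking: pd.DataFrame  # predictors, r2, aicc, delta_aicc

    @property
    def best(self) -> ModelFit:
        return self.fits[0]


def quarterly_specs(response: str = "p_annual_herb") -> list[ModelSpec]:
    """The 34 candidate specs: 4 temperature x 8 precipitation quarterly
    pairs plus the two yearly-mean baselines."""
    specs = []
    prec_terms = [*QUARTER_PREC_VARS, *[f"log({p}+1)" for p in QUARTER_PREC_VARS]]
    for t in QUARTER_TEMP_VARS:
        for p in prec_terms:
            specs.append(ModelSpec(response, (t, p)))
    specs.append(ModelSpec(response, ("bio1", "bio12")))
    specs.append(ModelSpec(response, ("bio1", "log(bio12+1)")))
    return specs


def quarterly_search(table: pd.DataFrame, response: str = "p_annual_herb") -> SearchResult:
    """Fit all 34 candidates and rank them by AICc (no interaction terms)."""
    fits = [fit_linear(spec, table) for spec in quarterly_specs(response)]
    fits.sort(key=lambda f: f.aicc)
    best = fits[0].aicc
    ranking = pd.DataFrame(
        {
            "predictors": [" + ".join(f.spec.predictors) for f in fits],
            "r2": [f.r2 for f in fits],
            "aicc": [f.aicc for f in fits],
            "delta_aicc": [f.aicc - best for f in fits],
        }
    )
    return SearchResult(fits=fits, ranking=ranking)


@dataclass
class ExtensionResult:
    base: ModelFit
    extended: ModelFit
    delta_aicc: float  # extended - base; negative = improvement
    delta_r2: float


def extend_model(base_spec: ModelSpec, extras: tuple[str, ...], table: pd.DataFrame) -> ExtensionResult:
    """Nested comparison of a base model and its extension on an identical
    case set (rows complete for *all* columns of the extended model)."""
    ext_spec = ModelSpec(base_spec.response, base_spec.predictors + tuple(extras), base_spec.family)
    cc = table.dropna(subset=sorted(ext_spec.columns()))
    base = fit_linear(base_spec, cc)
    ext = fit_linear(ext_spec, cc)
    return ExtensionResult(base=base, extended=ext, delta_aicc=ext.aicc - base.aicc, delta_r2=(ext.r2 or 0) - (base.r2 or 0))


def fit_per_family(
    tables: dict[str, pd.DataFrame], spec: ModelSpec, min_regions: int = 30
) -> dict[str, ModelFit]:
    """Refit one spec per family table; families with too few analysable
    regions are skipped with a warning."""
    out = {}
    for fam, table in tables.items():
        cc = table.dropna(subset=sorted(spec.columns()))
        if len(cc) < min_regions:
            warnings.warn(f"family {fam}: only {len(cc)} regions (<{min_regions}); skipped")
            continue
        out[fam] = fit_linear(spec, cc)
    return out


# --- alternative regressions ------------------------------------------------

def smoothed_logit(successes: pd.Series, totals: pd.Series) -> pd.Series:
    """Empirical logit with (x+0.5)/(n+1) shrinkage so boundary proportions
    (0 and 1) stay finite."""
    p = (successes + 0.5) / (totals + 1.0)
    return np.log(p / (1.0 - p))


def fit_alternatives(
    table: pd.DataFrame,
    predictors: tuple[str, ...],
    count_col: str = "n_annual_herb",
    total_col: str = "n_herb_species",
) -> dict[str, ModelFit]:
    """Logit-OLS and Poisson-offset alternatives to the linear proportion fit.

    logit: OLS on the smoothed empirical logit of count/total.
    poisson: GLM, response = count, offset = log(total), log link, so the
    fitted rate is a per-species annual proportion.
    Regions with a zero total are excluded.
    """
    cols = {count_col, total_col}
    for t in predictors:
        cols |= term_columns(t)
    cc = table.dropna(subset=sorted(cols))
    cc = cc[cc[total_col] > 0].copy()

    cc["_logit"] = smoothed_logit(cc[count_col], cc[total_col])
    logit_fit = fit_linear(ModelSpec("_logit", tuple(predictors)), cc)

    X = pd.DataFrame({"const": 1.0, **{t: eval_term(t, cc) for t in predictors}}, index=cc.index)
    y = cc[count_col].astype(float)
    res = sm.GLM(y, X, family=sm.families.Poisson(), offset=np.log(cc[total_col].astype(float))).fit()
    k = X.shape[1]  # no separate dispersion parameter in Poisson
    pois_fit = ModelFit(
        spec=ModelSpec(count_col, tuple(predictors), family="poisson-log-offset"),
        params=dict(res.params),
        bse=dict(res.bse),
        pvalues=dict(res.pvalues),
        r2=None,
        loglik=float(res.llf),
        aic=-2.0 * res.llf + 2.0 * k,
        aicc=_aicc_from_llf(res.llf, int(res.nobs), k),
        n=int(res.nobs),
        df_resid=int(res.df_resid),
        extra={"deviance": float(res.deviance), "fitted": res.fittedvalues},
    )
    return {"logit": logit_fit, "poisson": pois_fit}


# --- spatial eigenvectors (dbMEM) ------------------------------------------

@dataclass
class MEMBasis:
    """Selected Moran eigenvector map basis.

    ``vectors`` is an (n_regions x k) DataFrame of unit-norm, zero-mean,
    mutually orthogonal columns named mem1..memk, ordered by |eigenvalue|.
    """

    vectors: pd.DataFrame
    eigenvalues: np.ndarray
    truncation_km: float
    variance_share: float


def spatial_eigenvectors(
    lon: np.ndarray,
    lat: np.ndarray,
    variance_target: float = 0.8,
    index: pd.Index | None = None,
    duplicates: str = "error",
) -> MEMBasis:
    """Distance-based Moran eigenvector maps from region centroids.

    Great-circle distances are truncated at the longest edge of their
    minimum spanning tree (distances beyond it are set to 4x the threshold,
    the classical dbMEM recipe), the squared matrix is Gower
    double-centered, and the eigenvectors are selected in decreasing
    |eigenvalue| order — spanning both positive and negative spatial
    autocorrelation — until their cumulative |eigenvalue| share reaches
    ``variance_target``.
    """
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    if len(lon) < 3:
        raise ValueError("need at least 3 centroids")
    D = haversine_matrix(lon, lat)
    off = D[~np.eye(len(D), dtype=bool)]
    if (off == 0).any():
        if duplicates == "jitter":
            rngless = np.arange(len(lon)) * 1e-9
            D = haversine_matrix(lon + rngless, lat)
        else:
            raise ValueError("duplicate centroids; pass duplicates='jitter' to perturb")
    mst = minimum_spanning_tree(D)
    thresh = float(mst.data.max())
    Dt = np.where(D <= thresh, D, 4.0 * thresh)
    np.fill_diagonal(Dt, 0.0)
    A = -0.5 * Dt**2
    n = len(A)
    J = np.eye(n) - np.ones((n, n)) / n
    B = J @ A @ J
    B = (B + B.T) / 2.0
    w, V = np.linalg.eigh(B)
    keep = np.abs(w) > 1e-9 * np.abs(w).max()
    w, V = w[keep], V[:, keep]
    order = np.argsort(-np.abs(w))
    w, V = w[order], V[:, order]
    share = np.cumsum(np.abs(w)) / np.abs(w).sum()
    k = int(np.searchsorted(share, variance_target) + 1)
    idx = index if index is not None else pd.RangeIndex(n)
    vectors = pd.DataFrame(V[:, :k], index=idx, columns=[f"mem{i+1}" for i in range(k)])
    return MEMBasis(vectors=vectors, eigenvalues=w[:k], truncation_km=thresh, variance_share=float(share[k - 1]))


def morans_i(values: np.ndarray, lon: np.ndarray, lat: np.ndarray, threshold_km: float | None = None) -> float:
    """Moran's I of a variable over point locations with binary
    within-threshold neighbour weights (default threshold: longest MST edge)."""
    z = np.asarray(values, dtype=float)
    z = z - z.mean()
    D = haversine_matrix(lon, lat)
    if threshold_km is None:
        threshold_km = float(minimum_spanning_tree(D).data.max())
    W = ((D <= threshold_km) & (D > 0)).astype(float)
    s0 = W.sum()
    if s0 == 0 or (z**2).sum() == 0:
        return np.nan
    n = len(z)
    return float(n / s0 * (z @ W @ z) / (z**2).sum())


# --- phylogenetic GLS --------------------------------------------------------

def brownian_covariance(tree: dendropy.Tree, taxa: list[str]) -> np.ndarray:
    """Brownian-motion covariance (shared root-to-tip path lengths) for the
    given taxa, in their order. Unit rate; the GLS scales it."""
    idx = {label: i for i, label in enumerate(taxa)}
    n = len(taxa)
    V = np.zeros((n, n))
    depth: dict = {}
    tipsets: dict = {}
    for node in tree.preorder_node_iter():
        parent = node.parent_node
        depth[node] = (depth[parent] if parent else 0.0) + (node.edge.length or 0.0)
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            label = node.taxon.label
            tips = [idx[label]] if label in idx else []
            if tips:
                V[tips[0], tips[0]] = depth[node]
        else:
            child_tips = [tipsets[c] for c in node.child_nodes()]
            for a in range(len(child_tips)):
                for b in range(a + 1, len(child_tips)):
                    if child_tips[a] and child_tips[b]:
                        V[np.ix_(child_tips[a], child_tips[b])] = depth[node]
                        V[np.ix_(child_tips[b], child_tips[a])] = depth[node]
            tips = [t for ct in child_tips for t in ct]
        tipsets[node] = tips
    return V


def fit_pgls(
    tree: dendropy.Tree,
    table: pd.DataFrame,
    response: str,
    predictor: str = "annual",
) -> tuple[ModelFit, ModelFit]:
    """pGLS of a species-level response on a 0/1 life-cycle indicator.

    The error covariance is sigma2 * V with V the Brownian shared-path
    matrix from the supplied tree (branch lengths taken as given, no
    lambda/kappa transform); estimation is by V-whitened least squares.
    Returns ``(pgls_fit, ols_fit)`` — the companion ordinary regression
    quantifies the impact of phylogenetic relatedness.
    """
    cc = table.dropna(subset=[response, predictor])
    taxa = list(cc.index)
    V = brownian_covariance(tree, taxa)
    try:
        L = np.linalg.cholesky(V)
    except np.linalg.LinAlgError as err:
        raise ValueError("singular Brownian covariance (zero-length paths?)") from err

    X = np.column_stack([np.ones(len(cc)), cc[predictor].to_numpy(dtype=float)])
    y = cc[response].to_numpy(dtype=float)
    names = ["const", predictor]

    def gls_fit(Xw: np.ndarray, yw: np.ndarray, family: str, logdet: float) -> ModelFit:
        beta, _, _, _ = np.linalg.lstsq(Xw, yw, rcond=None)
        resid = yw - Xw @ beta
        n, p = Xw.shape
        rss = float(resid @ resid)
        sigma2_ml = rss / n
        llf = -0.5 * (n * np.log(2 * np.pi * sigma2_ml) + n + logdet)
        s2 = rss / (n - p)
        cov = s2 * np.linalg.inv(Xw.T @ Xw)
        bse = np.sqrt(np.diag(cov))
        from scipy import stats

        tvals = beta / bse
        pvals = 2 * stats.t.sf(np.abs(tvals), df=n - p)
        k = p + 1
        yc = yw - yw.mean()
        r2 = 1.0 - rss / float(yc @ yc) if float(yc @ yc) > 0 else np.nan
        return ModelFit(
            spec=ModelSpec(response, (predictor,), family=family),
            params=dict(zip(names, beta)),
            bse=dict(zip(names, bse)),
            pvalues=dict(zip(names, pvals)),
            r2=float(np.clip(r2, 0.0, 1.0)),
            loglik=float(llf),
            aic=-2.0 * llf + 2 * k,
            aicc=_aicc_from_llf(llf, n, k),
            n=n,
            df_resid=n - p,
        )

    logdet_V = 2.0 * float(np.sum(np.log(np.diag(L))))
    Xw = np.linalg.solve(L, X)
    yw = np.linalg.solve(L, y)
    pgls = gls_fit(Xw, yw, "pgls-brownian", logdet_V)
    ols = gls_fit(X, y, "gaussian-ols", 0.0)
    return pgls, ols


# --- GBIF sampling-bias diagnostics -----------------------------------------

def bias_diagnostics(
    table: pd.DataFrame,
    responses: tuple[str, ...] = ("p_annual", "p_annual_herb"),
    depth_col: str = "log10_total_obs",
    richness_col: str = "n_species",
) -> dict[str, ModelFit]:
    """Simple regressions of annual proportions on sampling depth
    (log10 total observations) and on present-species richness; slopes near
    zero indicate proportions are not artefacts of sampling effort."""
    out = {}
    for resp in responses:
        out[f"{resp}~{depth_col}"] = fit_linear(ModelSpec(resp, (depth_col,)), table)
        out[f"{resp}~{richness_col}"] = fit_linear(ModelSpec(resp, (richness_col,)), table)
    return out
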