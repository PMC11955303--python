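"""Smooth-term regression stage for event composition.

Two responses over multi-shark co-occurrence events, at either temporal
scale:

* event sex ratio, as a binomial (males, females) count pair — ratio 1 means
  all males;
* sqrt of the within-event fork-length range ("size variance"), Gaussian,
  square-root transformed against right skew, weighted by event shark count.

Predictors follow a common structure: smooth terms for total shark number
and year (B-spline bases, small basis dimension since only ~10 year levels
exist), month as a categorical term, and site as an intercept offset per
site (the stand-in for a penalized random intercept). Each full model is
compared with its intercept-only null via a generalized likelihood-ratio
test on the deviance scale.

The smoothing backend is `statsmodels` GLMGam; basis dimension and penalty
weight are configurable. Fitted coefficients are backend-dependent — the
contract here is term significance and the sign/shape of partial responses,
not exact coefficient reproduction.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.gam.api import BSplines, GLMGam

from .events import CoocEvent

log = logging.getLogger(__name__)

RESPONSES = ("sex_ratio_binomial", "sqrt_size_variance")
SEASON_MONTH_ORDER = (9, 10, 11, 12, 1, 2, 3, 4)


@dataclass
class ModelSpec:
    response: str
    scale: str = "deployment"
    include_n: bool = True
    include_year: bool = True
    include_month: bool = True
    include_site: bool = True
    k_n: int = 5
    k_year: int = 5
    alpha: float = 1.0
    month_reference: int = 10

    def __post_init__(self) -> None:
        if self.response not in RESPONSES:
            raise ValueError(f"response must be one of {RESPONSES}")

    def null_spec(self) -> "ModelSpec":
        return ModelSpec(response=self.response, scale=self.scale,
                         include_n=False, include_year=False,
                         include_month=False, include_site=False)


@dataclass
class TermSummary:
    name: str
    kind: str            # smooth | linear | categorical
    edf: float
    statistic: float
    p_value: float

    @property
    def significant(self) -> bool:
        return self.p_value <= 0.05


@dataclass
class ModelFit:
    spec: ModelSpec
    result: object
    terms: dict[str, TermSummary]
    deviance: float
    null_deviance: float
    n_obs: int
    total_edf: float
    converged: bool
    data: pd.DataFrame = field(repr=False, default=None)
    _design: dict = field(repr=False, default_factory=dict)
    _cov: np.ndarray = field(repr=False, default=None)

    @property
    def deviance_explained(self) -> float:
        if self.null_deviance <= 0:
            return 0.0
        return 1.0 - self.deviance / self.null_deviance

    def partial_slope(self, term: str = "n_sharks") -> float:
        """Sign-bearing linear trend of the fitted partial response."""
        x, y = self.partial_response(term)
        if len(np.unique(x)) < 2:
            return 0.0
        return float(np.polyfit(x, y, 1)[0])

    def partial_response(self, term: str) -> tuple[np.ndarray, np.ndarray]:
        info = self._design.get(term)
        if info is None:
            raise KeyError(f"term {term!r} not in model")
        x = self.data[term].to_numpy(dtype=float)
        if info["kind"] == "smooth":
            vals = info["basis"] @ np.asarray(self.result.params)[info["cols"]]
            order = np.argsort(x)
            return x[order], np.asarray(vals)[order]
        if info["kind"] == "linear":
            coef = self.result.params[info["cols"][0]]
            order = np.argsort(x)
            return x[order], coef * x[order]
        raise ValueError(f"partial response undefined for {info['kind']} term")

    def month_coefficients(self) -> dict[int, tuple[float, float, float]]:
        """month -> (coef, z, p) relative to the reference month."""
        info = self._design.get("month")
        if info is None:
            return {}
        out = {}
        params = np.asarray(self.result.params)
        if self._cov is not None:
            bse = np.sqrt(np.clip(np.diag(self._cov), 0, None))
        else:
            bse = np.asarray(self.result.bse)
        for month, col in zip(info["levels"], info["cols"]):
            z = params[col] / bse[col] if bse[col] > 0 else 0.0
            p = 2 * stats.norm.sf(abs(z))
            out[month] = (float(params[col]), float(z), float(p))
        return out

    def summary_table(self) -> pd.DataFrame:
        rows = [{"term": t.name, "kind": t.kind, "edf": t.edf,
                 "statistic": t.statistic, "p_value": t.p_value,
                 "significant": t.significant}
                for t in self.terms.values()]
        return pd.DataFrame(rows)


@dataclass
class LrtResult:
    deviance_difference: float
    df_difference: float
    p_value: float

    @property
    def significant(self) -> bool:
        return self.p_value <= 0.05

    def to_dict(self) -> dict:
        return {"deviance_difference": self.deviance_difference,
                "df_difference": self.df_difference,
                "p_value": self.p_value}


# --------------------------------------------------------------------------
# event table construction and month filter

def build_event_table(events: Sequence[CoocEvent]) -> pd.DataFrame:
    """Per-event modelling table (all events; fitting filters to n >= 2)."""
    rows = []
    for ev in events:
        fls = [m.fork_length_mm for m in ev.members
               if m.fork_length_mm is not None]
        n_m = sum(1 for m in ev.members if m.sex == "male")
        n_f = sum(1 for m in ev.members if m.sex == "female")
        rows.append({
            "event_id": ev.event_id,
            "site": ev.site,
            "year": ev.date.year,
            "month": ev.date.month,
            "n_sharks": ev.n,
            "n_male": n_m,
            "n_female": n_f,
            "n_fl": len(fls),
            "fl_range": (max(fls) - min(fls)) if len(fls) >= 2 else
                        (0.0 if fls else np.nan),
        })
    df = pd.DataFrame(rows)
    if len(df):
        df["sqrt_fl_range"] = np.sqrt(df["fl_range"])
    return df


def month_filter(
    event_table: pd.DataFrame,
    scale: str = "deployment",
    min_events_deployment: int = 4,
    min_events_simultaneous: int = 5,
) -> pd.DataFrame:
    """Drop months with too few events to estimate a month effect.

    Defaults follow the case-study choices: at deployment scale months with
    fewer than 4 events go (April had 3); at simultaneous scale months with
    fewer than 5 events go.
    """
    if "month" not in event_table.columns:
        raise ValueError("event table needs a month column")
    minimum = (min_events_deployment if scale == "deployment"
               else min_events_simultaneous)
    counts = event_table["month"].value_counts()
    keep = counts[counts >= minimum].index
    out = event_table[event_table["month"].isin(keep)].copy()
    if out.empty:
        raise ValueError("month filter removed every event")
    dropped = sorted(set(counts.index) - set(keep))
    if dropped:
        log.info("month filter dropped months %s at %s scale", dropped, scale)
    return out


# --------------------------------------------------------------------------
# fitting

def _season_sorted(months: Sequence[int]) -> list[int]:
    order = {m: i for i, m in enumerate(SEASON_MONTH_ORDER)}
    return sorted(set(months), key=lambda m: order.get(m, 99))


def _prepare(spec: ModelSpec, table: pd.DataFrame):
    df = table[table["n_sharks"] >= 2].copy()
    if spec.response == "sex_ratio_binomial":
        df = df[(df["n_male"] + df["n_female"]) >= 1]
        endog = df[["n_male", "n_female"]].to_numpy(dtype=float)
        family = sm.families.Binomial()
        var_weights = None
    else:
        df = df[df["n_fl"] >= 2]
        endog = df["sqrt_fl_range"].to_numpy(dtype=float)
        family = sm.families.Gaussian()
        var_weights = df["n_sharks"].to_numpy(dtype=float)
    if "weight" in df.columns:
        w = df["weight"].to_numpy(dtype=float)
        var_weights = w if var_weights is None else var_weights * w
    if len(df) < 3:
        raise ValueError(f"only {len(df)} usable events for {spec.response}")
    return df, endog, family, var_weights


def _fisher_inference(model, result, n_params: int,
                      penalized: bool) -> tuple[np.ndarray, np.ndarray]:
    """Per-parameter effective df and coefficient covariance.

    Both are derived from the weighted Fisher information A = X'WX, with W
    the final IRLS working weights (trials x mu(1-mu) for the binomial
    sex-ratio model, the variance weights for the Gaussian one) and S the
    smoothing penalty: edf = diag[(A+S)^-1 A] and
    cov = (A+S)^-1 A (A+S)^-1 * scale, the penalized sandwich. Computed
    in-package so that binomial trial counts enter the information — the
    fitting backend drops them from its own covariance.
    """
    X = model.exog
    mu = np.asarray(result.predict())
    if isinstance(model.family, sm.families.Binomial):
        # two-column endog is stored as proportions; trials live apart
        trials = getattr(model, "n_trials", None)
        if trials is None:
            trials = np.ones(len(mu))
        w = np.asarray(trials, dtype=float) * mu * (1 - mu)
        scale = 1.0
    else:
        w = np.ones(X.shape[0])
        scale = float(result.scale)
    vw = getattr(model, "var_weights", None)
    if vw is not None and np.ndim(vw) == 1:
        w = w * np.asarray(vw)
    A = X.T @ (X * w[:, None])
    if penalized:
        S = model.penal.penalty_matrix(alpha=model.alpha)
    else:
        S = np.zeros_like(A)
    Hinv = np.linalg.pinv(A + S)
    edf = np.clip(np.diag(Hinv @ A), 0.0, 1.0)
    cov = Hinv @ A @ Hinv * scale
    return edf, cov


def fit_model(spec: ModelSpec, table: pd.DataFrame) -> ModelFit:
    """Fit the configured model; see module docstring for the structure."""
    df, endog, family, var_weights = _prepare(spec, table)
    n = len(df)

    exog_cols: list[np.ndarray] = [np.ones(n)]
    exog_names = ["const"]
    design: dict[str, dict] = {}
    terms_order: list[tuple[str, str, list[int]]] = []

    def add_categorical(name: str, levels: list, codes: pd.Series,
                        reference) -> None:
        lv = [l for l in levels if l != reference]
        cols = []
        for level in lv:
            exog_cols.append((codes == level).to_numpy(dtype=float))
            exog_names.append(f"{name}[{level}]")
            cols.append(len(exog_names) - 1)
        if cols:
            design[name] = {"kind": "categorical", "cols": cols,
                            "levels": lv, "reference": reference}
            terms_order.append((name, "categorical", cols))

    if spec.include_site:
        sites = sorted(df["site"].unique())
        if len(sites) < 2:
            warnings.warn("single site level: site term dropped")
        else:
            add_categorical("site", sites, df["site"], sites[0])

    if spec.include_month:
        months = _season_sorted(df["month"])
        if len(months) >= 2:
            ref = (spec.month_reference if spec.month_reference in months
                   else months[0])
            add_categorical("month", months, df["month"], ref)

    smooth_vars: list[str] = []
    smooth_dfs: list[int] = []
    for name, include, k in (("n_sharks", spec.include_n, spec.k_n),
                             ("year", spec.include_year, spec.k_year)):
        if not include:
            continue
        x = df[name].to_numpy(dtype=float)
        nuniq = len(np.unique(x))
        if nuniq < 2:
            log.info("predictor %s constant: dropped", name)
            continue
        if nuniq < 5:
            # centre on the range midpoint: invariant to row weighting
            exog_cols.append(x - (x.min() + x.max()) / 2)
            exog_names.append(name)
            design[name] = {"kind": "linear", "cols": [len(exog_names) - 1]}
            terms_order.append((name, "linear", design[name]["cols"]))
        else:
            smooth_vars.append(name)
            smooth_dfs.append(int(min(k, nuniq - 1)))

    exog = np.column_stack(exog_cols)
    k_exog = exog.shape[1]

    penalized = False
    if smooth_vars:
        xs = df[smooth_vars].to_numpy(dtype=float)
        smoother = BSplines(xs, df=smooth_dfs, degree=[3] * len(smooth_vars),
                            include_intercept=False)
        basis_dims = [s.dim_basis for s in smoother.smoothers]
        col = k_exog
        basis_cols = np.cumsum([0] + basis_dims)
        for i, (name, dfree) in enumerate(zip(smooth_vars, basis_dims)):
            cols = list(range(col, col + dfree))
            basis = smoother.basis[:, basis_cols[i]:basis_cols[i + 1]]
            design[name] = {"kind": "smooth", "cols": cols,
                            "smooth_index": i, "basis": basis}
            terms_order.append((name, "smooth", cols))
            col += dfree
        n_params = col
        if var_weights is not None:
            # the GAM backend drops var_weights during fitting, so the
            # weighted (Gaussian) model takes the basis as plain columns;
            # no penalty is needed there (no separation pathology)
            model = sm.GLM(endog, np.column_stack([exog, smoother.basis]),
                           family=family, var_weights=var_weights)
            result = model.fit()
        else:
            model = GLMGam(endog, exog=exog, smoother=smoother,
                           alpha=[spec.alpha] * len(smooth_vars),
                           family=family)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                result = model.fit()
            penalized = spec.alpha > 0
    else:
        kwargs = {}
        if var_weights is not None:
            kwargs["var_weights"] = var_weights
        model = sm.GLM(endog, exog, family=family, **kwargs)
        result = model.fit()
        n_params = k_exog

    edf_arr, cov = _fisher_inference(model, result, n_params, penalized)
    params = np.asarray(result.params)

    terms: dict[str, TermSummary] = {}
    for name, kind, cols in terms_order:
        b = params[cols]
        V = cov[np.ix_(cols, cols)]
        try:
            statval = float(b @ np.linalg.solve(V, b))
            pval = float(stats.chi2.sf(statval, len(cols)))
        except np.linalg.LinAlgError:
            statval, pval = float("nan"), 1.0
        terms[name] = TermSummary(name=name, kind=kind,
                                  edf=float(edf_arr[cols].sum()),
                                  statistic=statval, p_value=pval)

    # null deviance on the same rows/weights
    null_kwargs = {}
    if var_weights is not None:
        null_kwargs["var_weights"] = var_weights
    null_res = sm.GLM(endog, np.ones((n, 1)), family=family,
                      **null_kwargs).fit()

    fit = ModelFit(
        spec=spec, result=result, terms=terms,
        deviance=float(result.deviance),
        null_deviance=float(null_res.deviance),
        n_obs=n, total_edf=float(edf_arr.sum()),
        converged=bool(getattr(result, "converged", True)),
        data=df, _design=design, _cov=cov)
    if not fit.converged:
        warnings.warn("model did not converge; downstream use is flagged")
    return fit


def fit_null_model(spec: ModelSpec, table: pd.DataFrame) -> ModelFit:
    """Intercept-only model on the same usable rows as the full model."""
    return fit_model(spec.null_spec(), table)


def lrt_vs_null(full: ModelFit, null: ModelFit) -> LrtResult:
    """Generalized likelihood-ratio test of the full model against its null.

    Deviance difference on the (scaled, for Gaussian) deviance scale against
    a chi-square with the effective-dimension difference as df.
    """
    if full.spec.response != null.spec.response:
        raise ValueError("responses differ: models are not nested")
    if full.n_obs != null.n_obs:
        raise ValueError("models were fit to different data")
    dev_diff = null.deviance - full.deviance
    if dev_diff < -1e-6 * max(1.0, null.deviance):
        raise ValueError("full model has larger deviance than null; not nested")
    dev_diff = max(dev_diff, 0.0)
    df_diff = max(full.total_edf - null.total_edf, 0.0)
    if full.spec.response == "sqrt_size_variance":
        scale = float(full.result.scale)
        stat = dev_diff / scale if scale > 0 else 0.0
    else:
        stat = dev_diff
    p = 1.0 if df_diff <= 0 else float(stats.chi2.sf(stat, df_diff))
    return LrtResult(deviance_difference=float(dev_diff),
                     df_difference=float(df_diff), p_value=p)


def fit_with_null(spec: ModelSpec,
                  table: pd.DataFrame) -> tuple[ModelFit, ModelFit, LrtResult]:
    full = fit_model(spec, table)
    null = fit_null_model(spec, table)
    return full, null, lrt_vs_null(full, null)


# --------------------------------------------------------------------------
# outlier sensitivity

@dataclass
class SensitivityResult:
    outlier_event_id: str
    fit_with: ModelFit
    fit_without: ModelFit
    slope_with: float
    slope_without: float

    @property
    def sign_flip(self) -> bool:
        return (self.slope_with * self.slope_without < 0
                and abs(self.slope_with) > 0 and abs(self.slope_without) > 0)

    def to_dict(self) -> dict:
        return {"outlier_event_id": self.outlier_event_id,
                "slope_with": self.slope_with,
                "slope_without": self.slope_without,
                "sign_flip": self.sign_flip}


def default_outlier_rule(table: pd.DataFrame) -> pd.DataFrame:
    """The largest mixed-sex event with the most extreme sex ratio."""
    mixed = table[(table["n_male"] > 0) & (table["n_female"] > 0)
                  & (table["n_sharks"] >= 2)]
    if mixed.empty:
        return mixed
    biggest = mixed[mixed["n_sharks"] == mixed["n_sharks"].max()].copy()
    ratio = biggest["n_male"] / (biggest["n_male"] + biggest["n_female"])
    biggest["_extremity"] = (ratio - 0.5).abs()
    return biggest[biggest["_extremity"] == biggest["_extremity"].max()] \
        .drop(columns="_extremity")


def sensitivity_without_outlier(
    spec: ModelSpec,
    event_table: pd.DataFrame,
    outlier_rule=None,
) -> SensitivityResult:
    """Refit with and without the outlying event; report the shark-number
    partial-response trend under both fits and whether its sign flips."""
    rule = outlier_rule or default_outlier_rule
    candidates = rule(event_table)
    if len(candidates) != 1:
        ids = list(candidates["event_id"]) if len(candidates) else []
        raise ValueError(
            f"outlier rule matched {len(candidates)} events "
            f"(need exactly 1): {ids}")
    out_id = candidates["event_id"].iloc[0]
    fit_with = fit_model(spec, event_table)
    fit_without = fit_model(
        spec, event_table[event_table["event_id"] != out_id])
    return SensitivityResult(
        outlier_event_id=out_id, fit_with=fit_with, fit_without=fit_without,
        slope_with=fit_with.partial_slope("n_sharks"),
        slope_without=fit_without.partial_slope("n_sharks"))
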