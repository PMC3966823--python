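"""Mixed-model inference on wetland neonicotinoid concentrations.

The response is the log-transformed total neonicotinoid concentration of a
wetland water sample, modelled over the post-baseline seasons with a
Gaussian linear mixed model:

    log(total + delta) ~ season * crop + baseline + previous-year crop
                         + (random quarter-section and wetland intercepts)

where ``delta`` (half the smallest LOQ by default) keeps non-detect totals
finite on the log scale, ``baseline`` is the pre-seeding (spring 2012)
log concentration, and quarter sections / wetlands-within-quarter-sections
carry random intercepts (optionally season-specific variances, optionally a
random time slope). Reference levels are summer 2012 and grassland.

Model selection among random-effect structures uses maximum-likelihood AIC;
the reported fit uses REML. Crop-by-season cell-mean differences are tested
with Wald chi-square interaction contrasts, with the family-wise error
controlled by the Dunn-Šidák correction (per-test level
``1 - (1 - alpha)^(1/k)``, always at least the Bonferroni level
``alpha/k``). A Mann-Whitney U comparison supports the check that wetlands
drying in fall resembled those staying wet.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

from .errors import (
    ConvergenceError,
    DegenerateStructureError,
    EmptyGroupError,
    EstimabilityError,
    InvalidParameterError,
    SelectionError,
)
from .residue_pipeline import LOQ_WATER_REPORTING, WetlandPanel

__all__ = [
    "LmmSpec",
    "LmmFit",
    "ContrastResult",
    "prepare_model_frame",
    "fit_lmm",
    "select_random_effects",
    "interaction_contrasts",
    "sidak_adjust",
    "mann_whitney_u",
]


# ---------------------------------------------------------------------------
# Specification and results
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LmmSpec:
    """Specification of the mixed model.

    ``random`` selects the random-effect structure:

    * ``"nested"`` — one intercept variance for quarter sections and one
      for wetlands nested within quarter sections;
    * ``"season_nested"`` — season-specific intercept variances for both
      levels (the structure of the reported variance table);
    * ``"none"`` — fixed effects only (ordinary least squares).

    ``delta`` is the offset added to totals before the log transform;
    ``None`` means half the smallest configured LOQ.
    """

    random: str = "season_nested"
    random_slope: bool = False
    include_interaction: bool = True
    include_baseline: bool = True
    include_prev_crop: bool = True
    season_ref: str = "summer2012"
    crop_ref: str = "grassland"
    delta: float | None = None
    reml: bool = True

    def __post_init__(self) -> None:
        if self.random not in {"nested", "season_nested", "none"}:
            raise InvalidParameterError(f"unknown random structure {self.random!r}")
        if self.delta is not None and not self.delta > 0:
            raise InvalidParameterError("delta must be positive")
        if self.random_slope and self.random == "none":
            raise InvalidParameterError("random slope requires a random structure")

    @property
    def label(self) -> str:
        return self.random + ("+slope" if self.random_slope else "")


@dataclass
class LmmFit:
    """Fitted mixed model: fixed effects, variance components, likelihood."""

    spec: LmmSpec
    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    cov_fe: pd.DataFrame
    vcomp: dict[str, float]
    resid_var: float
    llf: float
    aic: float
    n_params: int
    nobs: int
    converged: bool
    method: str

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "estimate": self.params,
                "se": self.bse,
                "t": self.tvalues,
                "p": self.pvalues,
            }
        )


@dataclass(frozen=True)
class ContrastResult:
    """One crop-by-season-pair cell-mean contrast (Wald chi-square, 1 df)."""

    crop: str
    season_pair: tuple[str, str]
    estimate: float
    chi2: float
    df: int
    p: float
    alpha_adjusted: float
    significant: bool

    @property
    def label(self) -> str:
        return f"{self.crop}: {self.season_pair[0]} vs {self.season_pair[1]}"


# ---------------------------------------------------------------------------
# Data preparation
# ---------------------------------------------------------------------------

def prepare_model_frame(
    panel: WetlandPanel,
    matrix: str = "water",
    baseline_season: str = "spring2012",
    delta: float | None = None,
) -> pd.DataFrame:
    """Build the response table for :func:`fit_lmm` from a residue panel.

    One row per (wetland, post-baseline season) with the log-transformed
    total, the baseline-season log total as a covariate, crop labels, a
    numeric season index ``time``, and the nesting identifiers. Wetlands
    never sampled in the baseline season get a baseline of log(delta)
    (no information, treated as non-detect).
    """
    if delta is None:
        delta = 0.5 * min(LOQ_WATER_REPORTING.values())
    samples = panel.samples
    sub = samples[samples["matrix"] == matrix].copy()
    if sub.empty:
        raise EmptyGroupError(f"no samples for matrix {matrix!r}")
    sub["log_total"] = np.log(sub["total"] + delta)
    base = (
        sub[sub["season"] == baseline_season]
        .set_index("wetland_id")["log_total"]
        .rename("baseline")
    )
    seasons = [s for s in panel.seasons if s != baseline_season and s in set(sub["season"])]
    out = sub[sub["season"].isin(seasons)].copy()
    out["baseline"] = out["wetland_id"].map(base).fillna(np.log(delta))
    out["time"] = out["season"].map({s: float(i) for i, s in enumerate(seasons)})
    cols = [
        "wetland_id",
        "qs_id",
        "season",
        "crop",
        "crop_prev",
        "time",
        "baseline",
        "total",
        "log_total",
    ]
    return out[cols].reset_index(drop=True)


def _dummies(values: pd.Series, ref: str, prefix: str) -> pd.DataFrame:
    levels = [l for l in pd.unique(values) if l != ref]
    if ref not in set(values):
        raise EstimabilityError(
            f"reference level {ref!r} absent from {prefix} labels"
        )
    return pd.DataFrame(
        {f"{prefix}[{l}]": (values == l).astype(float) for l in sorted(levels)},
        index=values.index,
    )


def _build_fixed_design(frame: pd.DataFrame, spec: LmmSpec) -> pd.DataFrame:
    """Treatment-coded fixed design with readable column names."""
    X = pd.DataFrame({"Intercept": np.ones(len(frame))}, index=frame.index)
    season_d = _dummies(frame["season"], spec.season_ref, "season")
    crop_d = _dummies(frame["crop"], spec.crop_ref, "crop")
    X = pd.concat([X, season_d, crop_d], axis=1)
    if spec.include_baseline:
        X["baseline"] = frame["baseline"].astype(float)
    if spec.include_prev_crop:
        prev = _dummies(frame["crop_prev"], spec.crop_ref, "crop_prev")
        X = pd.concat([X, prev], axis=1)
    if spec.include_interaction:
        for s_col in season_d.columns:
            for c_col in crop_d.columns:
                name = f"{s_col}:{c_col}"
                X[name] = season_d[s_col] * crop_d[c_col]
    return X


def _check_rank(X: pd.DataFrame) -> None:
    arr = X.to_numpy()
    rank = np.linalg.matrix_rank(arr)
    if rank < X.shape[1]:
        # name the aliased columns via the QR diagonal
        _, rmat = np.linalg.qr(arr)
        diag = np.abs(np.diag(rmat))
        tol = diag.max() * max(arr.shape) * np.finfo(float).eps
        aliased = [X.columns[i] for i in range(len(diag)) if diag[i] < tol]
        raise EstimabilityError(
            f"fixed design is rank deficient (rank {rank} < {X.shape[1]}); "
            f"aliased terms: {aliased or 'ordering-dependent'}"
        )


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

_OPTIMIZERS = ("lbfgs", "bfgs", "cg")


def fit_lmm(frame: pd.DataFrame, spec: LmmSpec, rtol: float = 1e-8) -> LmmFit:
    """Fit the Gaussian mixed model described by ``spec``.

    ``frame`` is a :func:`prepare_model_frame`-style table. Estimation is
    REML by default (``spec.reml=False`` for ML, as used in AIC model
    selection). Non-convergence after bounded optimizer restarts raises
    :class:`ConvergenceError`; a successful fit reports fixed-effect
    estimates, their covariance, and the random-effect variances.
    """
    frame = frame.reset_index(drop=True)
    y = frame["log_total"].astype(float)
    X = _build_fixed_design(frame, spec)
    _check_rank(X)

    if spec.random == "none":
        model = sm.OLS(y, X)
        res = model.fit()
        k = X.shape[1] + 1  # + residual variance
        llf = float(res.llf)
        return LmmFit(
            spec=spec,
            params=res.params,
            bse=res.bse,
            tvalues=res.tvalues,
            pvalues=res.pvalues,
            cov_fe=pd.DataFrame(res.cov_params(), index=X.columns, columns=X.columns),
            vcomp={},
            resid_var=float(res.scale),
            llf=llf,
            aic=-2.0 * llf + 2.0 * k,
            n_params=k,
            nobs=int(res.nobs),
            converged=True,
            method="ols",
        )

    groups = frame["qs_id"].astype(str)
    if groups.nunique() < 2:
        raise DegenerateStructureError(
            "need at least 2 quarter sections for a random intercept"
        )

    data = pd.concat([y.rename("log_total"), X, frame[["wetland_id", "season", "time"]]], axis=1)
    data["wetland_id"] = data["wetland_id"].astype(str)
    seasons = sorted(frame["season"].unique())
    for s in seasons:
        data[f"ind_{s}"] = (frame["season"] == s).astype(float)

    fixed_rhs = " + ".join(f"Q('{c}')" for c in X.columns if c != "Intercept")
    formula = "log_total ~ " + (fixed_rhs if fixed_rhs else "1")

    if spec.random == "nested":
        re_formula = "1 + time" if spec.random_slope else "1"
        vc_formula = {"wetland": "0 + C(wetland_id)"}
    else:  # season_nested
        re_formula = "0 + time" if spec.random_slope else "0"
        vc_formula = {}
        for s in seasons:
            vc_formula[f"qs:{s}"] = f"0 + ind_{s}"
            vc_formula[f"wetland:{s}"] = f"0 + C(wetland_id):ind_{s}"

    model = sm.MixedLM.from_formula(
        formula,
        data=data,
        groups=groups,
        re_formula=re_formula,
        vc_formula=vc_formula,
    )

    res = None
    last_exc: Exception | None = None
    for attempt, method in enumerate(_OPTIMIZERS):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                candidate = model.fit(reml=spec.reml, method=method, maxiter=500)
        except (np.linalg.LinAlgError, ValueError) as exc:
            last_exc = exc
            continue
        if candidate.converged:
            res = candidate
            break
        res = res or candidate
    if res is None:
        raise ConvergenceError(f"mixed-model fit failed: {last_exc}")

    k_fe = model.k_fe
    fe_names = list(X.columns)
    params = pd.Series(np.asarray(res.fe_params), index=fe_names)
    bse = pd.Series(np.asarray(res.bse_fe), index=fe_names)
    cov = pd.DataFrame(
        np.asarray(res.cov_params())[:k_fe, :k_fe], index=fe_names, columns=fe_names
    )
    tvals = params / bse
    pvals = pd.Series(2 * stats.norm.sf(np.abs(tvals)), index=fe_names)

    vcomp: dict[str, float] = {}
    if spec.random == "nested":
        vcomp["qs"] = float(np.asarray(res.cov_re)[0, 0])
        if spec.random_slope:
            vcomp["qs_slope"] = float(np.asarray(res.cov_re)[1, 1])
        for name, value in zip(model.exog_vc.names, np.asarray(res.vcomp)):
            vcomp[name] = float(value)
    else:
        if spec.random_slope:
            vcomp["qs_slope"] = float(np.asarray(res.cov_re)[0, 0])
        for name, value in zip(model.exog_vc.names, np.asarray(res.vcomp)):
            vcomp[name] = float(value)

    n_var = len(res.params) - k_fe + 1  # covariance params + residual variance
    k = k_fe + n_var
    llf = float(res.llf)
    return LmmFit(
        spec=spec,
        params=params,
        bse=bse,
        tvalues=tvals,
        pvalues=pvals,
        cov_fe=cov,
        vcomp=vcomp,
        resid_var=float(res.scale),
        llf=llf,
        aic=-2.0 * llf + 2.0 * k,
        n_params=k,
        nobs=len(frame),
        converged=bool(res.converged),
        method=f"mixedlm-{'reml' if spec.reml else 'ml'}",
    )


def select_random_effects(
    frame: pd.DataFrame, candidates: list[LmmSpec], tie_tol: float = 1e-6
) -> tuple[LmmSpec, pd.DataFrame]:
    """Choose a random-effect structure by maximum-likelihood AIC.

    All candidates are refit with ML on the same data; non-convergent
    candidates are excluded with a warning. Ties within ``tie_tol`` break
    toward the model with fewer parameters. Returns the winning spec
    (with ``reml=True`` restored for final fitting) and the AIC table.
    """
    if len(candidates) < 2:
        raise InvalidParameterError("need at least 2 candidate specifications")
    rows = []
    fits: list[tuple[LmmSpec, LmmFit]] = []
    for cand in candidates:
        ml_spec = replace(cand, reml=False)
        try:
            fit = fit_lmm(frame, ml_spec)
            ok = fit.converged
        except (ConvergenceError, np.linalg.LinAlgError) as exc:
            warnings.warn(f"candidate {cand.label} failed to fit: {exc}")
            fit, ok = None, False
        if fit is not None and not ok:
            warnings.warn(f"candidate {cand.label} did not converge; excluded")
        rows.append(
            {
                "model": cand.label,
                "n_params": fit.n_params if fit else np.nan,
                "aic": fit.aic if (fit and ok) else np.nan,
                "converged": ok,
            }
        )
        if fit is not None and ok:
            fits.append((cand, fit))
    table = pd.DataFrame(rows)
    if not fits:
        raise SelectionError("no candidate random-effect structure converged")
    best_aic = min(f.aic for _, f in fits)
    tied = [(c, f) for c, f in fits if f.aic - best_aic <= tie_tol]
    chosen = min(tied, key=lambda cf: cf[1].n_params)[0]
    return replace(chosen, reml=True), table


# ---------------------------------------------------------------------------
# Post-hoc contrasts
# ---------------------------------------------------------------------------

def _cell_vector(fit: LmmFit, crop: str, season: str) -> np.ndarray:
    """Fixed-effect loading of the (crop, season) cell mean (common covariates)."""
    spec = fit.spec
    names = list(fit.params.index)
    L = np.zeros(len(names))
    L[names.index("Intercept")] = 1.0

    def add(term: str) -> None:
        if term in names:
            L[names.index(term)] += 1.0
        else:
            raise EstimabilityError(
                f"cell ({crop}, {season}) not estimable: missing term {term!r}"
            )

    if season != spec.season_ref:
        add(f"season[{season}]")
    if crop != spec.crop_ref:
        add(f"crop[{crop}]")
    if spec.include_interaction and season != spec.season_ref and crop != spec.crop_ref:
        add(f"season[{season}]:crop[{crop}]")
    return L


def interaction_contrasts(
    fit: LmmFit,
    family: list[tuple[str, tuple[str, str]]] | None = None,
    alpha: float = 0.05,
) -> list[ContrastResult]:
    """Wald chi-square tests of season differences within crops.

    Each contrast compares the model-implied cell means of one crop in two
    seasons (holding covariates fixed), giving a 1-df chi-square. The
    family-wise level ``alpha`` is maintained over the ``k`` contrasts
    actually tested via the Dunn-Šidák per-test level.

    ``family`` defaults to every season pair for every crop present in the
    fitted fixed effects.
    """
    if not fit.converged:
        raise ConvergenceError("cannot test contrasts on a non-convergent fit")
    spec = fit.spec
    names = list(fit.params.index)
    if family is None:
        crops = sorted(
            {n.split("[")[1].rstrip("]") for n in names if n.startswith("crop[")}
        ) + [spec.crop_ref]
        seasons = sorted(
            {n.split("[")[1].split("]")[0] for n in names if n.startswith("season[")}
        ) + [spec.season_ref]
        family = [
            (crop, pair)
            for crop in sorted(crops)
            for pair in combinations(sorted(seasons), 2)
        ]
    k = len(family)
    if k < 1:
        raise InvalidParameterError("empty contrast family")
    alpha_adj = sidak_adjust(alpha, k)
    V = fit.cov_fe.to_numpy()
    beta = fit.params.to_numpy()
    out = []
    for crop, (s1, s2) in family:
        L = _cell_vector(fit, crop, s1) - _cell_vector(fit, crop, s2)
        est = float(L @ beta)
        var = float(L @ V @ L)
        if var <= 0 and est == 0.0:
            chi2 = 0.0
        elif var <= 0:
            raise EstimabilityError(
                f"contrast {crop}: {s1} vs {s2} has non-positive variance"
            )
        else:
            chi2 = est * est / var
        p = float(stats.chi2.sf(chi2, df=1)) if chi2 > 0 else 1.0
        out.append(
            ContrastResult(
                crop=crop,
                season_pair=(s1, s2),
                estimate=est,
                chi2=chi2,
                df=1,
                p=p,
                alpha_adjusted=alpha_adj,
                significant=p < alpha_adj,
            )
        )
    return out


def sidak_adjust(alpha: float, k: int) -> float:
    """Dunn-Šidák per-test level for ``k`` tests at family-wise ``alpha``.

    ``1 - (1 - alpha)**(1/k)``; always between the Bonferroni level
    ``alpha/k`` and ``alpha``.
    """
    if not (0.0 < alpha < 1.0):
        raise InvalidParameterError(f"alpha must lie in (0, 1), got {alpha}")
    if not (isinstance(k, (int, np.integer)) and k >= 1):
        raise InvalidParameterError(f"k must be an integer >= 1, got {k}")
    return float(1.0 - (1.0 - alpha) ** (1.0 / k))


# ---------------------------------------------------------------------------
# Mann-Whitney comparison (dried vs wet wetlands)
# ---------------------------------------------------------------------------

def mann_whitney_u(group_a, group_b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Returns ``(U_a, p)`` where ``U_a`` counts (a, b) pairs with a > b plus
    half the ties. The p-value is exact for small untied samples
    (min(n) <= 8) and otherwise uses the tie-corrected normal
    approximation with continuity correction.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise EmptyGroupError("both groups must be non-empty")
    has_ties = len(np.unique(np.concatenate([a, b]))) < a.size + b.size
    method = "exact" if (min(a.size, b.size) <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method=method, use_continuity=True
    )
    return float(res.statistic), float(res.pvalue)
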