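"""Environmental models: predictor screening, all-subsets Gaussian GLMs with
AIC model averaging, metric correlations, species-area fits and the
EDGE-by-IUCN ANOVA.

The modelling protocol mirrors standard multimodel inference on gridded
diversity surfaces: responses (except sesPD) are log10 transformed, all
variables are z-scored over the analysis domain so slopes are comparable,
every subset of the screened predictors is fitted by Gaussian maximum
likelihood, and models within ``delta_max`` AIC of the best are combined by
Akaike weights using full (shrinkage) averaging: a model that omits a
predictor contributes a zero estimate for it.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .core_data import COVARIATES, DataError, MetricSurface

#: responses that stay on their natural scale (z-scores already)
NO_LOG_RESPONSES = ("sesPD",)


# ---------------------------------------------------------------------------
# screening and transforms


def screen_predictors(
    cell_table: pd.DataFrame,
    predictors: list[str] | None = None,
    rho_max: float = 0.7,
) -> list[str]:
    """Drop predictors until all pairwise Spearman |rho| < rho_max.

    Deterministic rule: find the pair with the largest |rho| at or above the
    cutoff and drop its member with the larger mean absolute correlation to
    all other retained predictors (ties break toward the later column).
    """
    retained = list(predictors if predictors is not None else COVARIATES)
    missing = [p for p in retained if p not in cell_table.columns]
    if missing:
        raise DataError(f"predictors absent from cell table: {missing}")
    while len(retained) > 1:
        rho = (
            cell_table[retained]
            .corr(method="spearman")
            .abs()
            .to_numpy()
        )
        np.fill_diagonal(rho, 0.0)
        i, j = np.unravel_index(np.argmax(rho), rho.shape)
        if rho[i, j] < rho_max:
            break
        mean_i = rho[i].sum() / (len(retained) - 1)
        mean_j = rho[j].sum() / (len(retained) - 1)
        drop = retained[j] if mean_j >= mean_i else retained[i]
        retained.remove(drop)
    return retained


def transform_and_standardize(
    surfaces: dict[str, MetricSurface],
    cell_table: pd.DataFrame,
    predictors: list[str] | None = None,
) -> pd.DataFrame:
    """Build the standardized model frame over the surfaces' cell domain.

    Responses other than sesPD are log10 transformed (erroring on
    non-positive values, which cannot occur on the occupied-cell domain),
    then every response and predictor is centred and scaled to unit
    variance.  Zero-variance columns are an error.
    """
    predictors = list(predictors if predictors is not None else COVARIATES)
    domains = {tuple(s.values.index) for s in surfaces.values()}
    if len(domains) != 1:
        raise DataError("surfaces do not share a cell domain")
    cells = list(next(iter(domains)))
    missing = [c for c in cells if c not in cell_table.index]
    if missing:
        raise DataError(f"cells absent from cell table: {missing[:5]}")

    frame = pd.DataFrame(index=pd.Index(cells, name="cell_id"))
    for name, surface in surfaces.items():
        values = surface.values.to_numpy(dtype=float)
        if name not in NO_LOG_RESPONSES:
            if (values <= 0).any():
                bad = surface.values.index[values <= 0][0]
                raise DataError(
                    f"cannot log10 metric {name!r}: non-positive value at "
                    f"cell {bad!r}"
                )
            values = np.log10(values)
        frame[name] = values
    for p in predictors:
        frame[p] = cell_table.loc[cells, p].to_numpy(dtype=float)

    sd = frame.std(ddof=1)
    flat = sd.index[(sd == 0) | sd.isna()].tolist()
    if flat:
        raise DataError(f"zero-variance columns cannot be standardized: {flat}")
    return (frame - frame.mean()) / sd


# ---------------------------------------------------------------------------
# all-subsets Gaussian GLMs


@dataclass(frozen=True)
class FittedModel:
    """One least-squares fit: intercept plus a subset of predictors."""

    predictors: tuple[str, ...]
    coefficients: pd.Series  # index: ['intercept', *predictors]
    std_errors: pd.Series
    rss: float
    aic: float
    r_squared: float
    adj_r_squared: float
    n: int


def _fit_ols(y: np.ndarray, x: pd.DataFrame, terms: tuple[str, ...]) -> FittedModel:
    n = len(y)
    design = np.column_stack([np.ones(n)] + [x[t].to_numpy() for t in terms])
    k = len(terms)
    beta, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    rss = float(resid @ resid)
    tss = float(((y - y.mean()) ** 2).sum())
    # Gaussian ML with profiled variance; parameter count k slopes +
    # intercept + sigma, so the penalty is 2(k + 2).
    aic = n * np.log(2 * np.pi) + n * np.log(rss / n) + n + 2 * (k + 2)
    sigma2 = rss / (n - k - 1)
    cov = sigma2 * np.linalg.inv(design.T @ design)
    se = np.sqrt(np.diag(cov))
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - k - 1)
    names = ["intercept", *terms]
    return FittedModel(
        predictors=terms,
        coefficients=pd.Series(beta, index=names),
        std_errors=pd.Series(se, index=names),
        rss=rss,
        aic=float(aic),
        r_squared=r2,
        adj_r_squared=adj_r2,
        n=n,
    )


def all_subsets_glm(
    response: str,
    frame: pd.DataFrame,
    predictors: list[str],
) -> list[FittedModel]:
    """Fit every subset of *predictors* (2^p models, intercept-only included)."""
    y = frame[response].to_numpy(dtype=float)
    n = len(y)
    if n <= len(predictors) + 2:
        raise DataError(
            f"n = {n} too small for {len(predictors)} predictors"
        )
    models: list[FittedModel] = []
    for size in range(len(predictors) + 1):
        for terms in combinations(predictors, size):
            models.append(_fit_ols(y, frame, terms))
    return models


# ---------------------------------------------------------------------------
# model averaging


@dataclass
class ModelAverageResult:
    """Model-averaged coefficients over the AIC-retained model set."""

    coefficients: pd.DataFrame  # estimate, se, z, p per term
    retained: pd.DataFrame  # per retained model: terms, aic, delta, weight
    best_adj_r_squared: float
    best_aic: float


def model_average(
    models: list[FittedModel],
    delta_max: float = 2.0,
    conditional: bool = False,
) -> ModelAverageResult:
    """Average coefficients over models with AIC within *delta_max* of the best.

    Akaike weights w_i are proportional to exp(-delta_i / 2).  Full
    averaging (default): a predictor absent from a model contributes a zero
    estimate with zero standard error there; the unconditional standard
    error is sum_i w_i sqrt(se_i^2 + (b_i - b_bar)^2) and p-values use the
    normal approximation.  ``conditional`` averages only over the models
    containing each term, with renormalized weights.
    """
    if not models:
        raise DataError("no models to average")
    aics = np.array([m.aic for m in models])
    best = aics.min()
    keep = [m for m, a in zip(models, aics) if a - best < delta_max]
    deltas = np.array([m.aic - best for m in keep])
    w = np.exp(-deltas / 2.0)
    w /= w.sum()

    terms = ["intercept"]
    for m in keep:
        for t in m.predictors:
            if t not in terms:
                terms.append(t)

    rows = {}
    for term in terms:
        betas = np.array(
            [m.coefficients.get(term, 0.0) for m in keep]
        )
        ses = np.array([m.std_errors.get(term, 0.0) for m in keep])
        present = np.array([term == "intercept" or term in m.predictors for m in keep])
        if conditional and term != "intercept":
            wc = w[present] / w[present].sum()
            beta_bar = float(wc @ betas[present])
            se_bar = float(
                wc @ np.sqrt(ses[present] ** 2 + (betas[present] - beta_bar) ** 2)
            )
        else:
            beta_bar = float(w @ betas)
            se_bar = float(w @ np.sqrt(ses**2 + (betas - beta_bar) ** 2))
        z = beta_bar / se_bar if se_bar > 0 else 0.0
        p = 2.0 * stats.norm.sf(abs(z))
        rows[term] = {"estimate": beta_bar, "se": se_bar, "z": z, "p": p}
    coefficients = pd.DataFrame.from_dict(rows, orient="index")
    coefficients.index.name = "term"

    best_model = min(keep, key=lambda m: m.aic)
    retained = pd.DataFrame(
        {
            "terms": ["+".join(m.predictors) or "(intercept)" for m in keep],
            "aic": [m.aic for m in keep],
            "delta_aic": deltas,
            "weight": w,
            "adj_r_squared": [m.adj_r_squared for m in keep],
        }
    ).sort_values("aic", ignore_index=True)
    return ModelAverageResult(
        coefficients=coefficients,
        retained=retained,
        best_adj_r_squared=best_model.adj_r_squared,
        best_aic=best_model.aic,
    )


def model_average_response(
    response: str,
    frame: pd.DataFrame,
    predictors: list[str],
    delta_max: float = 2.0,
) -> ModelAverageResult:
    """Convenience: all-subsets fit plus averaging for one response."""
    return model_average(all_subsets_glm(response, frame, predictors), delta_max)


# ---------------------------------------------------------------------------
# correlations, species-area, ANOVA


def spearman_matrix(surfaces: dict[str, MetricSurface]) -> pd.DataFrame:
    """Pairwise Spearman correlations of metric surfaces on a shared domain."""
    domains = {tuple(s.values.index) for s in surfaces.values()}
    if len(domains) != 1:
        raise DataError("surfaces do not share a cell domain")
    frame = pd.DataFrame({name: s.values for name, s in surfaces.items()})
    return frame.corr(method="spearman")


@dataclass(frozen=True)
class SpeciesAreaFit:
    """log10 richness ~ log10 area power-law fit."""

    slope: float
    intercept: float
    adj_r_squared: float
    p_value: float


def species_area_fit(islands: pd.DataFrame) -> SpeciesAreaFit:
    """OLS of log10(richness) on log10(area) over islands.

    ``islands`` needs positive ``area`` and ``richness`` columns and at
    least 3 rows.
    """
    if not {"area", "richness"}.issubset(islands.columns):
        raise DataError("island table needs 'area' and 'richness' columns")
    if len(islands) < 3:
        raise DataError("need at least 3 islands")
    if (islands[["area", "richness"]] <= 0).any().any():
        raise DataError("areas and richness must be positive")
    x = np.log10(islands["area"].to_numpy(dtype=float))
    y = np.log10(islands["richness"].to_numpy(dtype=float))
    fit = stats.linregress(x, y)
    n = len(x)
    r2 = fit.rvalue**2
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    return SpeciesAreaFit(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        adj_r_squared=float(adj),
        p_value=float(fit.pvalue),
    )


def anova_edge_by_category(species_scores: pd.DataFrame) -> tuple[float, float]:
    """One-way ANOVA of species EDGE scores across IUCN categories.

    DD species (no EDGE score) are excluded.  Requires at least two
    categories with at least two species each.
    """
    scored = species_scores.dropna(subset=["EDGE"])
    groups = [
        g["EDGE"].to_numpy()
        for _, g in scored.groupby("iucn")
        if len(g) >= 2
    ]
    if len(groups) < 2:
        raise DataError("need >= 2 IUCN categories with >= 2 scored species")
    f, p = stats.f_oneway(*groups)
    return float(f), float(p)
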