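"""The five multilevel outcome analyses.

Each analyzed outcome gets a Group x Time x Activity factorial fixed-effects
structure (sum-to-zero +-1 contrasts, first levels gyoza/pre/gyoza coded +1),
a family matched to its data type, and a participant-level random structure
chosen by AIC between a random intercept and a random intercept plus random
time slope:

======================  =========  =======================  =================
outcome                 family     response / weight        random structure
======================  =========  =======================  =================
survey                  binomial   proportion / n items     AIC-selected
recall (composite)      binomial   proportion / n units     AIC-selected
recognition             binomial   proportion / 20 trials   AIC-selected
order                   binomial   proportion / 66 trials   AIC-selected
segmentation_count      poisson    press count              AIC-selected
segmentation_agreement  gaussian   correlation r            intercept only,
                                                            + count covariate
======================  =========  =======================  =================

Estimated marginal (least-squares) means average the linear predictor over
the non-focal factors with equal cell weights on the link scale, then apply
the inverse link; SEs use the delta method. Pairwise contrasts are Wald
tests of link-scale differences.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd
from scipy import stats

from .glmm import MixedGLMResult, fit_mixed_glm
from .simulate import GYOZA, PRE

FACTORS = ("group", "time", "activity")
FACTOR_LEVELS = {
    "group": (GYOZA, "taichi"),
    "time": (PRE, "post"),
    "activity": (GYOZA, "taichi"),
}
TERMS = (
    "(Intercept)",
    "group",
    "time",
    "activity",
    "group:time",
    "group:activity",
    "time:activity",
    "group:time:activity",
)

OUTCOMES = (
    "survey",
    "recall",
    "recognition",
    "order",
    "segmentation_count",
    "segmentation_agreement",
)


@dataclass(frozen=True)
class ModelSpec:
    """Declarative model definition for one outcome."""

    outcome: str
    family: str
    weighted: bool
    covariates: tuple[str, ...] = ()
    candidate_structures: tuple[str, ...] = ("intercept", "intercept_slope")

    @property
    def terms(self) -> tuple[str, ...]:
        return TERMS + self.covariates


@dataclass
class FitResult:
    """A fitted outcome model plus the spec and chosen random structure."""

    spec: ModelSpec
    result: MixedGLMResult
    chosen_structure: str
    candidate_aics: dict[str, float] = field(default_factory=dict)
    covariate_means: dict[str, float] = field(default_factory=dict)

    @property
    def aic(self) -> float:
        return self.result.aic

    def coef_table(self) -> pd.DataFrame:
        return self.result.coef_table()


def build_model_spec(outcome: str) -> ModelSpec:
    """The analysis specification for one of the six outcome measures."""
    if outcome in ("survey", "recall", "recognition", "order"):
        return ModelSpec(outcome=outcome, family="binomial", weighted=True)
    if outcome == "segmentation_count":
        return ModelSpec(outcome=outcome, family="poisson", weighted=False)
    if outcome == "segmentation_agreement":
        return ModelSpec(
            outcome=outcome,
            family="gaussian",
            weighted=False,
            covariates=("seg_count",),
            candidate_structures=("intercept",),
        )
    raise ValueError(f"unknown outcome {outcome!r}")


def code_factor(values: pd.Series, factor: str) -> np.ndarray:
    """Sum-to-zero codes: first level +1, second level -1."""
    first, second = FACTOR_LEVELS[factor]
    codes = np.where(values == first, 1.0, np.where(values == second, -1.0, np.nan))
    if np.any(np.isnan(codes)):
        bad = sorted(set(values) - set(FACTOR_LEVELS[factor]))
        raise ValueError(f"unknown {factor} levels: {bad}")
    return codes


def design_matrix(data: pd.DataFrame, covariates: tuple[str, ...] = ()) -> tuple[np.ndarray, list[str]]:
    """Factorial design matrix with sum-coded factors plus raw covariates."""
    g = code_factor(data["group"], "group")
    t = code_factor(data["session"], "time")
    a = code_factor(data["activity"], "activity")
    cols = [np.ones(len(data)), g, t, a, g * t, g * a, t * a, g * t * a]
    names = list(TERMS)
    for cov in covariates:
        cols.append(data[cov].to_numpy(dtype=float))
        names.append(cov)
    return np.column_stack(cols), names


def _prepare(spec: ModelSpec, data: pd.DataFrame):
    data = data.reset_index(drop=True)
    X, names = design_matrix(data, spec.covariates)
    if spec.outcome in ("survey", "recall", "recognition", "order"):
        y = data["proportion"].to_numpy(dtype=float)
        weights = data["trials"].to_numpy(dtype=float)
    elif spec.outcome == "segmentation_count":
        y = data["count"].to_numpy(dtype=float)
        weights = None
    else:
        y = data["r"].to_numpy(dtype=float)
        weights = None
    participants, group_idx = np.unique(data["participant"], return_inverse=True)
    slope = (data["session"] == "post").to_numpy(dtype=float)
    return X, names, y, weights, group_idx, slope


def fit_multilevel(
    spec: ModelSpec,
    data: pd.DataFrame,
    *,
    random: str | None = "intercept",
) -> FitResult:
    """Fit one outcome model with a given random structure.

    ``data`` is complete-case long-format: one row per participant x session
    x activity with the response, the trial weight (binomial), and any
    covariates. ``random=None`` fits the fixed-effects-only (zero random
    variance) limit.
    """
    X, names, y, weights, group_idx, slope = _prepare(spec, data)
    result = fit_mixed_glm(
        X, y, group_idx,
        family=spec.family, weights=weights, random=random,
        slope=slope, fixed_names=names,
    )
    if not result.converged:
        raise RuntimeError(
            f"{spec.outcome} model with random={random!r} did not converge"
        )
    cov_means = {c: float(data[c].mean()) for c in spec.covariates}
    return FitResult(
        spec=spec, result=result,
        chosen_structure=random if random is not None else "none",
        covariate_means=cov_means,
    )


def select_random_structure(spec: ModelSpec, data: pd.DataFrame) -> FitResult:
    """Fit every candidate random structure and keep the lowest-AIC fit.

    Ties (within 1e-6) go to the simpler structure; candidates that fail to
    converge are dropped, and if none converge the error propagates.
    """
    fits: dict[str, FitResult] = {}
    errors: list[str] = []
    for structure in spec.candidate_structures:
        try:
            fits[structure] = fit_multilevel(spec, data, random=structure)
        except (RuntimeError, np.linalg.LinAlgError) as exc:  # non-convergence
            errors.append(f"{structure}: {exc}")
    if not fits:
        raise RuntimeError(
            f"no candidate random structure converged for {spec.outcome}: {errors}"
        )
    aics = {s: f.aic for s, f in fits.items()}
    # candidate order encodes simplicity: earlier = simpler
    best = min(
        fits,
        key=lambda s: (aics[s] - 1e-6 * (spec.candidate_structures.index(s) == 0)),
    )
    chosen = fits[best]
    chosen.candidate_aics = aics
    return chosen


# ---------------------------------------------------------------------------
# Marginal means and contrasts


@dataclass
class EmmGrid:
    """Estimated marginal means over a set of focal factors."""

    factors: tuple[str, ...]
    cells: pd.DataFrame  # factor columns + M, SE (response scale)
    link_rows: np.ndarray  # design rows on the link scale, one per cell
    link_means: np.ndarray
    fit: FitResult

    def cell_index(self, **levels: str) -> int:
        mask = np.ones(len(self.cells), dtype=bool)
        for f, lvl in levels.items():
            mask &= (self.cells[f] == lvl).to_numpy()
        idx = np.flatnonzero(mask)
        if idx.size != 1:
            raise KeyError(f"cell {levels!r} not uniquely in grid")
        return int(idx[0])


def _inverse_link(family: str, eta: np.ndarray) -> np.ndarray:
    if family == "binomial":
        return 1.0 / (1.0 + np.exp(-eta))
    if family == "poisson":
        return np.exp(eta)
    return eta


def _dmu_deta(family: str, eta: np.ndarray) -> np.ndarray:
    if family == "binomial":
        mu = 1.0 / (1.0 + np.exp(-eta))
        return mu * (1.0 - mu)
    if family == "poisson":
        return np.exp(eta)
    return np.ones_like(eta)


def marginal_means(fit: FitResult, factors: tuple[str, ...] = FACTORS) -> EmmGrid:
    """Least-squares means for each combination of the focal factors.

    The full group x time x activity grid is built with sum-coded design
    rows (covariates held at their data means); rows are averaged with equal
    weight over the non-focal factors on the link scale, transformed through
    the inverse link, with delta-method SEs from the fixed-effect covariance.
    """
    unknown = set(factors) - set(FACTORS)
    if unknown:
        raise ValueError(f"unknown factors: {sorted(unknown)}")
    spec = fit.spec
    full = pd.DataFrame(
        [dict(zip(FACTORS, combo)) for combo in product(*(FACTOR_LEVELS[f] for f in FACTORS))]
    )
    full = full.rename(columns={"time": "session"})
    full["session"] = full["session"]
    frame = pd.DataFrame(
        {
            "group": full["group"],
            "session": full["session"],
            "activity": full["activity"],
        }
    )
    for cov in spec.covariates:
        frame[cov] = fit.covariate_means[cov]
    rows, _ = design_matrix(frame, spec.covariates)

    focal_levels = [FACTOR_LEVELS[f] for f in factors]
    cells = []
    link_rows = []
    frame_factors = frame.rename(columns={"session": "time"})
    for combo in product(*focal_levels):
        mask = np.ones(len(frame), dtype=bool)
        for f, lvl in zip(factors, combo):
            mask &= (frame_factors[f] == lvl).to_numpy()
        link_rows.append(rows[mask].mean(axis=0))
        cells.append(dict(zip(factors, combo)))
    link_rows = np.asarray(link_rows)
    beta = fit.result.beta
    cov_beta = fit.result.cov_beta
    eta = link_rows @ beta
    se_eta = np.sqrt(np.einsum("ij,jk,ik->i", link_rows, cov_beta, link_rows))
    mu = _inverse_link(spec.family, eta)
    se_mu = np.abs(_dmu_deta(spec.family, eta)) * se_eta
    table = pd.DataFrame(cells)
    table["M"] = mu
    table["SE"] = se_mu
    return EmmGrid(
        factors=tuple(factors), cells=table, link_rows=link_rows,
        link_means=eta, fit=fit,
    )


def contrast(emm: EmmGrid, cell_a: dict[str, str], cell_b: dict[str, str]):
    """Pairwise contrast between two grid cells (link-scale Wald test).

    Returns ``(estimate, se, statistic, p)`` where the estimate is the
    link-scale difference a - b.
    """
    i = emm.cell_index(**cell_a)
    j = emm.cell_index(**cell_b)
    d = emm.link_rows[i] - emm.link_rows[j]
    result = emm.fit.result
    est = float(d @ result.beta)
    se = float(np.sqrt(d @ result.cov_beta @ d))
    if se == 0.0:
        return est, se, 0.0, 1.0
    s = est / se
    if result.stat_name == "z":
        p = float(2.0 * stats.norm.sf(abs(s)))
    else:
        p = float(2.0 * stats.t.sf(abs(s), df=result.df_resid))
    return est, se, s, p


def pairwise_contrasts(emm: EmmGrid) -> pd.DataFrame:
    """All pairwise contrasts between grid cells."""
    rows = []
    cells = emm.cells[list(emm.factors)].to_dict("records")
    for i in range(len(cells)):
        for j in range(i + 1, len(cells)):
            est, se, s, p = contrast(emm, cells[i], cells[j])
            rows.append(
                {
                    "cell_a": "/".join(cells[i].values()),
                    "cell_b": "/".join(cells[j].values()),
                    "estimate": est,
                    "SE": se,
                    emm.fit.result.stat_name: s,
                    "p": p,
                }
            )
    return pd.DataFrame(rows)
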