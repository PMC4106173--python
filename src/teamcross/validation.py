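"""Predictive-ability assessment: cross-validation, external trials, loss.

The predictive value of a marker model is judged four ways:

* **generalized Jackknife cross-validation** — remove all plots of k
  randomly chosen hybrids, refit, predict the removed hybrids, and
  correlate predictions with their fixed-effect-adjusted observed means;
  repeated over many draws per imbalance level, the pooled correlations
  are summarized by mean, median and kernel-density mode;
* **external validation** — predictions for hybrids grown in independent
  regional trials (new year, new locations) are regressed on the regional
  adjusted means (linear and quadratic fits);
* **per-parent fits** — within each parental family (parents with enough
  crosses) a separate regression measures how line-specific the
  predictive credibility is;
* **selection loss** — a 0/1 loss over a truncation selection: how many
  of the observed-best hybrids a prediction-based selection captures, and
  how many predicted-best are observed discards.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .design import adjusted_hybrid_means, check_phenotypes, design_from_columns
from .matrices import AdditiveMatrix, DominanceMatrix
from .panel import split_hybrid_id
from .team import TeamModel

logger = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# correlation summaries
# --------------------------------------------------------------------------

def summarize_correlations(samples) -> tuple[float, float, float]:
    """Mean, median and kernel-density mode of correlation samples.

    The mode is the argmax of a Gaussian kernel density (Silverman
    bandwidth) evaluated on a 512-point grid over [-1, 1]; a degenerate
    (constant) sample's mode is that constant.
    """
    arr = np.asarray([s for s in samples if np.isfinite(s)], dtype=float)
    if arr.size == 0:
        raise ValueError("no finite correlation samples to summarize")
    mean = float(np.mean(arr))
    median = float(np.median(arr))
    if arr.size < 2 or np.std(arr) == 0:
        return mean, median, float(arr[0])
    kde = gaussian_kde(arr, bw_method="silverman")
    grid = np.linspace(-1.0, 1.0, 512)
    mode = float(grid[int(np.argmax(kde(grid)))])
    return mean, median, mode


def regression_r2(predicted, observed, degree: int = 1) -> float:
    """Coefficient of determination of a polynomial OLS fit."""
    x = np.asarray(predicted, dtype=float)
    y = np.asarray(observed, dtype=float)
    if degree not in (1, 2):
        raise ValueError("degree must be 1 or 2")
    if x.size < degree + 2:
        raise ValueError(f"need at least {degree + 2} points for degree {degree}")
    if np.std(y) == 0:
        raise ValueError("constant observed values: R2 undefined")
    coef = np.polyfit(x, y, degree)
    resid = y - np.polyval(coef, x)
    return float(1.0 - (resid @ resid) / ((y - y.mean()) @ (y - y.mean())))


# --------------------------------------------------------------------------
# Jackknife cross-validation
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CVConfig:
    """Imbalance levels (hybrid counts or fractions), draws, model, seed."""

    levels: tuple = (0.05, 0.10, 0.15, 0.20, 0.25, 0.30, 0.35, 0.43, 0.51)
    draws: int = 500
    variant: str = "TEAM2"
    seed: int = 0
    tol: float = 1e-8
    max_iter: int = 2000

    def __post_init__(self):
        if self.draws < 1:
            raise ValueError("draws must be >= 1")
        for lev in self.levels:
            if isinstance(lev, float) and not lev.is_integer():
                if not 0 < lev < 1:
                    raise ValueError(f"fractional level {lev} outside (0, 1)")
            elif int(lev) < 1:
                raise ValueError(f"level {lev} must be a positive count")


@dataclass
class CVLevelResult:
    k: int
    fraction: float
    samples: list[float] = field(default_factory=list)
    n_skipped: int = 0

    def summary(self) -> tuple[float, float, float]:
        if not self.samples:
            return (math.nan, math.nan, math.nan)
        return summarize_correlations(self.samples)


@dataclass
class CVResult:
    levels: list[CVLevelResult]
    variant: str

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for lev in self.levels:
            mean, median, mode = lev.summary()
            rows.append(
                {
                    "k": lev.k,
                    "pct_missing": round(100 * lev.fraction),
                    "mean": mean,
                    "median": median,
                    "mode": mode,
                    "n_draws": len(lev.samples),
                    "n_skipped": lev.n_skipped,
                }
            )
        return pd.DataFrame(rows)


def jackknife_cv(
    pheno: pd.DataFrame,
    A: AdditiveMatrix,
    D: DominanceMatrix | None,
    config: CVConfig,
) -> CVResult:
    """Leave-k-hybrids-out cross-validation of a TEAM model.

    Per draw, every plot of k randomly chosen hybrids is removed, the
    model is refit on the remainder, and the removed hybrids' predicted
    genetic values are correlated with their observed fixed-effect-
    adjusted means.  When the number of distinct k-subsets does not exceed
    `draws` the enumeration is exhaustive (the classical Jackknife
    partition is a subset of this); otherwise subsets are sampled without
    replacement within a draw.  Draws whose refit does not converge or
    whose correlation is undefined are skipped and logged, never imputed.
    """
    pheno = check_phenotypes(pheno)
    hybrids = sorted(set(pheno["hybrid"]))
    n_h = len(hybrids)
    if n_h < 4:
        raise ValueError("cross-validation needs at least 4 hybrids")
    pos = {h: i for i, h in enumerate(A.hybrids)}
    missing = [h for h in hybrids if h not in pos]
    if missing:
        raise ValueError(f"design matrices lack hybrids: {missing[:5]}")

    results = []
    for lev in config.levels:
        k = int(lev) if (not isinstance(lev, float) or lev.is_integer()) else int(
            round(lev * n_h)
        )
        if k < 2:
            raise ValueError(f"imbalance level {lev}: k={k} leaves <2 validation hybrids")
        if n_h - k < 2:
            raise ValueError(f"imbalance level {lev}: only {n_h - k} training hybrids")
        n_subsets = math.comb(n_h, k)
        level_res = CVLevelResult(k=k, fraction=k / n_h)
        if n_subsets <= config.draws:
            subsets = list(combinations(range(n_h), k))
        else:
            rng = np.random.default_rng([config.seed, k])
            subsets = [
                tuple(sorted(rng.choice(n_h, size=k, replace=False)))
                for _ in range(config.draws)
            ]
        for subset in subsets:
            held = [hybrids[i] for i in subset]
            held_mask = pheno["hybrid"].isin(held)
            train = pheno.loc[~held_mask]
            model = TeamModel(
                variant=config.variant, tol=config.tol, max_iter=config.max_iter
            ).fit(train, A, D)
            if not model.result_.converged:
                level_res.n_skipped += 1
                logger.warning("CV refit did not converge for held set %s", held[:3])
                continue
            rows = [pos[h] for h in held]
            A_held = AdditiveMatrix(held, A.columns, A.values[rows])
            D_held = None
            if config.variant == "TEAM2":
                D_held = DominanceMatrix(
                    held,
                    D.columns,
                    D.values[rows],
                    coverage=D.coverage.iloc[rows] if D.coverage is not None else None,
                )
            pred = model.predict(A_held, D_held)["total"]
            held_pheno = pheno.loc[held_mask]
            X_held = design_from_columns(held_pheno, model.x_columns_)
            obs = adjusted_hybrid_means(held_pheno, beta=model.beta_, x_design=X_held)
            obs = obs.reindex(pred.index)
            if np.std(pred) == 0 or np.std(obs) == 0:
                level_res.n_skipped += 1
                logger.warning("undefined CV correlation for held set %s", held[:3])
                continue
            level_res.samples.append(float(np.corrcoef(pred, obs)[0, 1]))
        results.append(level_res)
    return CVResult(levels=results, variant=config.variant)


# --------------------------------------------------------------------------
# selection loss
# --------------------------------------------------------------------------

@dataclass
class SelectionLossResult:
    """Outcome of truncation selection compared between two rankings."""

    fraction: float
    n_selected: int
    selected_by_prediction: list[str]
    selected_by_observation: list[str]
    correct_rate: float  # observed-best captured / observed-best
    wrong_rate: float  # predicted-best that are observed discards / predicted-best
    wrong_rate_discard_basis: float  # same numerator / observed discards
    loss: pd.Series  # 0/1 per predicted-selected hybrid


def _top_fraction(values: pd.Series, n_sel: int) -> list[str]:
    order = sorted(values.items(), key=lambda kv: (-kv[1], kv[0]))
    return [h for h, _ in order[:n_sel]]


def selection_loss(
    predicted: pd.Series, observed: pd.Series, fraction: float = 0.20
) -> SelectionLossResult:
    """0/1 selection loss of a prediction-based truncation selection.

    The top ``ceil(fraction * N)`` hybrids by each ranking are selected
    (ties broken by hybrid identifier, stable).  The correct-selection
    rate is the share of observed-selected hybrids that the prediction
    also selected; the wrong-selection rate is the share of
    prediction-selected hybrids that the observation discarded (the
    alternative rate with observed discards as denominator is also
    reported).
    """
    if not 0 < fraction < 1:
        raise ValueError("selection fraction must be in (0, 1)")
    idx = predicted.index.sort_values()
    if set(idx) != set(observed.index):
        raise ValueError("predicted and observed cover different hybrids")
    predicted = predicted.reindex(idx)
    observed = observed.reindex(idx)
    n = len(idx)
    n_sel = math.ceil(fraction * n)
    sel_pred = _top_fraction(predicted, n_sel)
    sel_obs = _top_fraction(observed, n_sel)
    obs_set = set(sel_obs)
    discards = set(idx) - obs_set
    hits = [h for h in sel_pred if h in obs_set]
    wrong = [h for h in sel_pred if h in discards]
    loss = pd.Series({h: 0 if h in obs_set else 1 for h in sel_pred}, name="loss")
    return SelectionLossResult(
        fraction=fraction,
        n_selected=n_sel,
        selected_by_prediction=sel_pred,
        selected_by_observation=sel_obs,
        correct_rate=len(hits) / len(sel_obs),
        wrong_rate=len(wrong) / len(sel_pred),
        wrong_rate_discard_basis=len(wrong) / len(discards) if discards else 0.0,
        loss=loss,
    )


# --------------------------------------------------------------------------
# per-parent and external validation
# --------------------------------------------------------------------------

def per_parent_fit(
    predicted: pd.Series, observed: pd.Series, min_crosses: int = 4
) -> pd.DataFrame:
    """Family-wise linear fit: R2 per parent with >= `min_crosses` hybrids."""
    common = predicted.index.intersection(observed.index)
    fam: dict[str, list[str]] = {}
    for h in common:
        for parent in split_hybrid_id(h):
            fam.setdefault(parent, []).append(h)
    rows = []
    for parent in sorted(fam):
        members = fam[parent]
        if len(members) < min_crosses:
            continue
        r2 = regression_r2(predicted[members], observed[members], degree=1)
        rows.append({"parent": parent, "n_crosses": len(members), "r2": r2})
    return pd.DataFrame(rows, columns=["parent", "n_crosses", "r2"])


@dataclass
class ExternalValidation:
    n_overlap: int
    r2_linear: float
    r2_quadratic: float
    correlation: float
    selection: SelectionLossResult


def external_validate(
    predicted: pd.Series,
    regional: pd.DataFrame,
    fraction: float = 0.20,
) -> ExternalValidation:
    """Validate predictions against an independent regional trial.

    Regional plot yields are reduced to fixed-effect-adjusted hybrid means
    (new environments, estimated internally), joined to the predictions on
    hybrid identity, and compared by linear/quadratic regression fits, the
    realized correlation, and truncation-selection loss.
    """
    regional = check_phenotypes(regional)
    means = adjusted_hybrid_means(regional)
    overlap = predicted.index.intersection(means.index)
    if len(overlap) < 3:
        raise ValueError(f"only {len(overlap)} hybrids overlap the regional trial")
    pred = predicted.reindex(overlap).astype(float)
    obs = means.reindex(overlap).astype(float)
    return ExternalValidation(
        n_overlap=len(overlap),
        r2_linear=regression_r2(pred, obs, degree=1),
        r2_quadratic=regression_r2(pred, obs, degree=2),
        correlation=float(np.corrcoef(pred, obs)[0, 1]),
        selection=selection_loss(pred, obs, fraction=fraction),
    )
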