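"""Total effects of associated markers (TEAM): ridge-BLUP marker models.

Instead of modelling combining abilities of specific parents, the TEAM
approach assigns a random effect to every marker allele (additive) and to
every realized allele pair (dominance deviation) and fits them jointly in
the mixed model

    y = X b + A a + D d + e

at plot level, with environments/replicates/blocks fixed in ``X``.  TEAM1
carries only the additive term; TEAM2 adds the dominance term.  Effects
shrink like ridge regression (one common variance per term), and any
hybrid — tested or not — is predicted by summing the effects its parental
alleles carry.  Marker-by-environment interaction is deliberately left in
the residual.

The recovered total genetic variance uses the marker-effect sums of
squares plus the trace correction from the inverse mixed-model
coefficient-matrix blocks:

    s2_a = (sum_j a_j^2 + tr(W_n^-1) s2) / n
    s2_d = (sum_j d_j^2 + tr(W_k^-1) s2) / k
    s2_g = n s2_a + k s2_d.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.base import BaseEstimator

from .design import check_phenotypes, fixed_effects_design, hybrid_incidence
from .matrices import AdditiveMatrix, DominanceMatrix
from .mme import MixedModelFit, ModelSpec, RandomTerm, reml_em

ADDITIVE, DOMINANCE = "additive", "dominance"
VARIANTS = ("TEAM1", "TEAM2")


@dataclass(frozen=True)
class MarkerVariances:
    """Recovered marker-variance summary of a TEAM fit (t2.ha-2)."""

    sigma2_a: float
    sigma2_d: float
    n: int
    k: int

    @property
    def sigma2_g(self) -> float:
        return self.n * self.sigma2_a + self.k * self.sigma2_d


def recover_marker_variances(fit: MixedModelFit, n: int, k: int) -> MarkerVariances:
    """Total genetic variance from marker-effect solutions and traces."""
    if ADDITIVE not in fit.effects:
        raise ValueError("fit has no additive marker term")
    if fit.inv_block_trace.get(ADDITIVE) is None:
        raise ValueError("fit lacks inverse coefficient-matrix blocks")
    s2 = fit.components.residual
    a = fit.effects[ADDITIVE]
    s2_a = (float(a @ a) + fit.inv_block_trace[ADDITIVE] * s2) / n
    if DOMINANCE in fit.effects and k > 0:
        d = fit.effects[DOMINANCE]
        s2_d = (float(d @ d) + fit.inv_block_trace[DOMINANCE] * s2) / k
    else:
        s2_d = 0.0
    return MarkerVariances(sigma2_a=s2_a, sigma2_d=s2_d, n=n, k=max(k, 0))


class TeamModel(BaseEstimator):
    """Ridge-BLUP estimator of per-allele and per-allele-pair effects.

    Parameters
    ----------
    variant : {"TEAM2", "TEAM1"}
        TEAM1 fits additive allele effects only; TEAM2 adds dominance
        (allele-pair) deviations.
    tol, max_iter : EM-REML convergence settings.
    method : mixed-model solver backend ("auto", "direct", "cells").

    Attributes (after fit)
    ----------------------
    additive_effects_ : Series indexed by (marker, allele)
    dominance_effects_ : Series indexed by (marker, allele-pair); TEAM2 only
    components_ : VarianceComponents of the plot-level mixed model
    marker_variances_ : MarkerVariances (s2_a, s2_d, s2_g)
    beta_, x_columns_ : fixed-effect solutions and their labels
    training_hybrids_ : hybrids present in the training phenotypes
    result_ : full MixedModelFit
    """

    def __init__(
        self,
        variant: str = "TEAM2",
        tol: float = 1e-8,
        max_iter: int = 2000,
        method: str = "auto",
    ):
        self.variant = variant
        self.tol = tol
        self.max_iter = max_iter
        self.method = method

    def fit(
        self,
        pheno: pd.DataFrame,
        A: AdditiveMatrix,
        D: DominanceMatrix | None = None,
    ):
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")
        if self.variant == "TEAM2" and D is None:
            raise ValueError("TEAM2 requires a dominance matrix")
        pheno = check_phenotypes(pheno)
        X, x_names = fixed_effects_design(pheno)
        H, _ = hybrid_incidence(pheno, A.hybrids)  # errors on misaligned hybrids
        z_add = H @ sp.csr_matrix(A.values.astype(float))
        terms = [RandomTerm(ADDITIVE, z_add, list(A.columns))]
        if self.variant == "TEAM2":
            if D.hybrids != A.hybrids:
                raise ValueError("additive and dominance hybrid rows are misaligned")
            z_dom = H @ sp.csr_matrix(D.values.astype(float))
            terms.append(RandomTerm(DOMINANCE, z_dom, list(D.columns)))
        spec = ModelSpec(
            y=pheno["yield"].to_numpy(), X=X, terms=terms, x_columns=x_names
        )
        fit = reml_em(
            spec, tol=self.tol, max_iter=self.max_iter, method=self.method
        )
        self.result_ = fit
        self.components_ = fit.components
        self.beta_ = fit.beta
        self.x_columns_ = x_names
        self.allele_index_ = list(A.columns)
        self.additive_effects_ = pd.Series(
            fit.effects[ADDITIVE],
            index=pd.Index(self.allele_index_, tupleize_cols=False),
            name="additive_effect",
        )
        if self.variant == "TEAM2":
            self.pair_index_ = list(D.columns)
            self.dominance_effects_ = pd.Series(
                fit.effects[DOMINANCE],
                index=pd.Index(self.pair_index_, tupleize_cols=False),
                name="dominance_effect",
            )
            k = len(self.pair_index_)
        else:
            self.pair_index_ = []
            self.dominance_effects_ = pd.Series(dtype=float, name="dominance_effect")
            k = 0
        self.training_hybrids_ = sorted(set(pheno["hybrid"]))
        self.marker_variances_ = recover_marker_variances(
            fit, n=len(self.allele_index_), k=k
        )
        return self

    def _check_fitted(self):
        if not hasattr(self, "result_"):
            raise AttributeError("TeamModel is not fitted")

    def predict(
        self, A_rows: AdditiveMatrix, D_rows: DominanceMatrix | None = None
    ) -> pd.DataFrame:
        """Genetic values of the hybrids described by the given design rows.

        Rows must be built against this model's allele/pair indexes (see
        `build_additive_matrix(..., allele_index=model.allele_index_)`).
        Allele pairs unseen in training contribute zero to the dominance
        value; the `dominance_coverage` column reports the fraction of each
        hybrid's markers whose pair was in training.
        """
        self._check_fitted()
        if list(A_rows.columns) != self.allele_index_:
            raise ValueError("additive rows are not aligned to the trained index")
        alpha = A_rows.values.astype(float) @ self.additive_effects_.to_numpy()
        out = pd.DataFrame({"alpha": alpha}, index=A_rows.hybrids)
        if self.variant == "TEAM2":
            if D_rows is None:
                raise ValueError("TEAM2 prediction requires dominance rows")
            if list(D_rows.columns) != self.pair_index_:
                raise ValueError("dominance rows are not aligned to the trained index")
            out["delta"] = D_rows.values.astype(float) @ self.dominance_effects_.to_numpy()
            cov = D_rows.coverage
            out["dominance_coverage"] = (
                cov.to_numpy() if cov is not None else np.nan
            )
        else:
            out["delta"] = 0.0
            out["dominance_coverage"] = np.nan
        out["total"] = out["alpha"] + out["delta"]
        out.index.name = "hybrid"
        return out[["alpha", "delta", "total", "dominance_coverage"]]

    def training_values(self, A: AdditiveMatrix, D: DominanceMatrix | None = None):
        """Predicted genetic values of the training hybrids."""
        return self.predict(A, D if self.variant == "TEAM2" else None)


def fit_team(
    pheno: pd.DataFrame,
    A: AdditiveMatrix,
    D: DominanceMatrix | None = None,
    variant: str = "TEAM2",
    tol: float = 1e-8,
    max_iter: int = 2000,
) -> TeamModel:
    """Fit a TEAM marker model; thin wrapper over `TeamModel`."""
    return TeamModel(variant=variant, tol=tol, max_iter=max_iter).fit(pheno, A, D)
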