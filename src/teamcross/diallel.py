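"""Two-group partial-diallel analysis of multi-environment hybrid trials.

The phenotypic model decomposes plot yield into fixed environment/
replicate/block effects plus random general combining abilities of the two
heterotic groups (GCA1, GCA2), the specific combining ability of each cross
(SCA), the environment interactions of all three, and a residual:

    y = X b + Z1 a1 + Z2 a2 + Z3 d + Z4 i1 + Z5 i2 + Z6 w + e.

Variance components are estimated by EM-REML; a hybrid's genotypic value is
the BLUP sum GCA(parent1) + GCA(parent2) + SCA(cross).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd
from sklearn.base import BaseEstimator

from .design import check_phenotypes, factor, fixed_effects_design, incidence
from .mme import MixedModelFit, ModelSpec, RandomTerm, VarianceComponents, reml_em
from .panel import CrossSet, LinePanel

logger = logging.getLogger(__name__)

GCA1, GCA2, SCA = "gca1", "gca2", "sca"
GCA1xE, GCA2xE, SCAxE = "gca1xE", "gca2xE", "scaxE"


def build_diallel_spec(
    pheno: pd.DataFrame, crosses: CrossSet, panel: LinePanel
) -> ModelSpec:
    """Assemble the six-random-term diallel model from plot data.

    With a single environment the three interaction terms are dropped
    (with a logged warning) since they would be confounded with the main
    terms and the residual.
    """
    pheno = check_phenotypes(pheno)
    parents = crosses.parents_by_group(panel)
    seen = set(pheno["hybrid"])
    known = set(parents.index)
    if not seen <= known:
        raise ValueError(f"phenotypes reference unknown hybrids: {sorted(seen - known)[:5]}")

    X, x_names = fixed_effects_design(pheno)
    p1 = pheno["hybrid"].map(parents["parent1"])
    p2 = pheno["hybrid"].map(parents["parent2"])
    c1, lev1 = factor(p1)
    c2, lev2 = factor(p2)
    cs, levs = factor(pheno["hybrid"])
    terms = [
        RandomTerm(GCA1, incidence(c1, len(lev1)), lev1),
        RandomTerm(GCA2, incidence(c2, len(lev2)), lev2),
        RandomTerm(SCA, incidence(cs, len(levs)), levs),
    ]
    ce, leve = factor(pheno["environment"])
    if len(leve) > 1:
        for label, codes, levels in (
            (GCA1xE, c1, lev1),
            (GCA2xE, c2, lev2),
            (SCAxE, cs, levs),
        ):
            cross_codes = codes * len(leve) + ce
            cross_levels = [f"{l}:{e}" for l in levels for e in leve]
            terms.append(
                RandomTerm(label, incidence(cross_codes, len(cross_levels)), cross_levels)
            )
    else:
        logger.warning(
            "single-environment data: genotype-by-environment terms dropped"
        )
    return ModelSpec(y=pheno["yield"].to_numpy(), X=X, terms=terms, x_columns=x_names)


def heritability(
    components: VarianceComponents, n_environments: int, n_replicates: int
) -> float:
    """Entry-mean heritability of hybrid means at the trial's replication.

    h2 = s2_g / (s2_g + s2_gxe / E + s2_resid / (E r)), with s2_g the sum
    of the GCA1, GCA2 and SCA components and s2_gxe the sum of their
    environment interactions.
    """
    c = components.by_term
    s2_g = c.get(GCA1, 0.0) + c.get(GCA2, 0.0) + c.get(SCA, 0.0)
    s2_gxe = c.get(GCA1xE, 0.0) + c.get(GCA2xE, 0.0) + c.get(SCAxE, 0.0)
    denom = (
        s2_g
        + s2_gxe / n_environments
        + components.residual / (n_environments * n_replicates)
    )
    if denom <= 0:
        raise ValueError("zero phenotypic variance of entry means")
    return s2_g / denom


@dataclass
class DiallelSummary:
    """Variance components, heritability and per-hybrid genotypic BLUPs."""

    fit: MixedModelFit
    components: VarianceComponents
    sigma2_g: float
    h2: float
    hybrid_blups: pd.Series  # GCA(i) + GCA(j) + SCA(i, j)
    gca1: pd.Series
    gca2: pd.Series
    sca: pd.Series


class DiallelModel(BaseEstimator):
    """EM-REML estimator for the two-group diallel mixed model.

    Parameters
    ----------
    tol : float
        Relative-change convergence tolerance of the EM iteration.
    max_iter : int
        Iteration cap; non-convergence is flagged, not raised.

    Attributes (after fit)
    ----------------------
    components_ : VarianceComponents
    sigma2_g_ : float, total genetic variance (GCA1 + GCA2 + SCA)
    heritability_ : float, entry-mean basis
    hybrid_blups_ : Series of genotypic values per hybrid
    result_ : MixedModelFit
    """

    def __init__(self, tol: float = 1e-8, max_iter: int = 2000):
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, pheno: pd.DataFrame, crosses: CrossSet, panel: LinePanel):
        pheno = check_phenotypes(pheno)
        spec = build_diallel_spec(pheno, crosses, panel)
        fit = reml_em(spec, tol=self.tol, max_iter=self.max_iter)
        c = fit.components
        parents = crosses.parents_by_group(panel)
        g1 = pd.Series(fit.effects[GCA1], index=spec.terms[0].levels)
        g2 = pd.Series(fit.effects[GCA2], index=spec.terms[1].levels)
        sc = pd.Series(fit.effects[SCA], index=spec.terms[2].levels)
        blups = pd.Series(
            {
                h: g1[parents.at[h, "parent1"]] + g2[parents.at[h, "parent2"]] + sc[h]
                for h in sc.index
            },
            name="genotypic_blup",
        )
        n_env = pheno["environment"].nunique()
        n_rep = pheno.groupby("environment")["replicate"].nunique().max()
        self.components_ = c
        self.sigma2_g_ = (
            c.by_term.get(GCA1, 0.0) + c.by_term.get(GCA2, 0.0) + c.by_term.get(SCA, 0.0)
        )
        self.heritability_ = heritability(c, n_env, int(n_rep))
        self.hybrid_blups_ = blups
        self.gca1_, self.gca2_, self.sca_ = g1, g2, sc
        self.result_ = fit
        return self

    def summary(self) -> DiallelSummary:
        if not hasattr(self, "result_"):
            raise AttributeError("model is not fitted")
        return DiallelSummary(
            fit=self.result_,
            components=self.components_,
            sigma2_g=self.sigma2_g_,
            h2=self.heritability_,
            hybrid_blups=self.hybrid_blups_,
            gca1=self.gca1_,
            gca2=self.gca2_,
            sca=self.sca_,
        )


def fit_diallel(
    pheno: pd.DataFrame,
    crosses: CrossSet,
    panel: LinePanel,
    tol: float = 1e-8,
    max_iter: int = 2000,
) -> DiallelSummary:
    """Fit the two-group diallel model; thin wrapper over `DiallelModel`."""
    return DiallelModel(tol=tol, max_iter=max_iter).fit(pheno, crosses, panel).summary()
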