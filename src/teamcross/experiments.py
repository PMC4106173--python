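"""Reproducible study-scale simulation experiments.

These compose the generator and the estimators into the two headline
computational experiments of the package:

* `variance_recovery_experiment` — repeated synthetic partial-diallel
  trials at the replication preset, each analysed by the EM-REML diallel
  model; reports per-replicate and mean variance-component estimates, the
  basis for parameter-recovery claims.
* `external_validation_experiment` — a marker-truth training trial, a
  TEAM fit, and an independently grown regional trial of the same (plus
  new) hybrids, quantifying how far predictive agreement transfers across
  environments under strong genotype-by-environment interaction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .diallel import fit_diallel
from .matrices import build_additive_matrix, build_dominance_matrix
from .panel import CrossSet
from .prediction import predict_all_crosses
from .simulate import (
    GeneratingVariances,
    MarkerSpec,
    TrialSpec,
    replication_preset,
    simulate_cross_set,
    simulate_line_panel,
    simulate_trial,
)
from .team import TeamModel
from .validation import external_validate


def variance_recovery_experiment(
    n_replicates: int = 50,
    base_seed: int = 1,
    n_lines_group1: int = 27,
    n_lines_group2: int = 24,
    n_crosses: int = 58,
    trial: TrialSpec | None = None,
    variances: GeneratingVariances | None = None,
    tol: float = 1e-8,
    max_iter: int = 2000,
) -> pd.DataFrame:
    """Repeated diallel-truth simulations analysed by EM-REML.

    Replicate r uses seed ``base_seed + r`` for the panel, the cross set
    and the trial, so the default reproduces replicate seeds 1..50.
    Returns one row per replicate with the estimated GCA/SCA variance
    components, convergence information, and the generating values.
    """
    trial = trial or TrialSpec()
    v = variances or replication_preset()
    rows = []
    for r in range(n_replicates):
        seed = base_seed + r
        panel = simulate_line_panel(
            n_lines_group1, n_lines_group2, MarkerSpec(), seed=seed
        )
        crosses, _ = simulate_cross_set(panel, n_crosses, seed=seed)
        pheno, _ = simulate_trial(
            crosses, trial, v, "diallel-truth", panel, seed=seed
        )
        summary = fit_diallel(pheno, crosses, panel, tol=tol, max_iter=max_iter)
        c = summary.components.by_term
        rows.append(
            {
                "seed": seed,
                "gca1": c["gca1"],
                "gca2": c["gca2"],
                "sca": c["sca"],
                "residual": summary.components.residual,
                "heritability": summary.h2,
                "converged": summary.fit.converged,
                "n_iter": summary.fit.n_iter,
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["generating"] = {
        "gca1": v.sigma2_gca1, "gca2": v.sigma2_gca2, "sca": v.sigma2_sca
    }
    return out


@dataclass
class ExternalExperimentResult:
    training_heritability: float
    training_fit_r: float  # corr(TEAM fitted values, true genetic values)
    external_correlation: float  # corr(predictions, regional adjusted means)
    external_r2_linear: float
    external_r2_quadratic: float
    correct_rate: float
    wrong_rate: float
    n_overlap: int


def external_validation_experiment(
    seed: int = 1,
    n_new_hybrids: int = 117,
    regional_environments: int = 6,
    variances: GeneratingVariances | None = None,
    max_iter: int = 2000,
    selection_fraction: float = 0.20,
) -> ExternalExperimentResult:
    """Train TEAM2 on a year-1 trial; validate on an independent year-2 trial.

    The training trial is the replication layout (58 between-group crosses,
    7 environments x 2 replicates) in marker-truth mode.  The regional
    trial re-grows those hybrids plus `n_new_hybrids` new crosses of the
    same lines in fresh environments, reusing the genetic ground truth but
    redrawing all environment, interaction and residual terms.  Training
    heritability comes from the diallel analysis of the year-1 data.
    """
    v = variances or replication_preset()
    panel = simulate_line_panel(27, 24, MarkerSpec(), seed=seed)
    crosses, _ = simulate_cross_set(panel, 58, seed=seed)
    train_pheno, truth = simulate_trial(
        crosses, TrialSpec(), v, "marker-truth", panel, seed=seed
    )

    A = build_additive_matrix(panel, crosses)
    D = build_dominance_matrix(panel, crosses)
    model = TeamModel("TEAM2", max_iter=max_iter).fit(train_pheno, A, D)
    fitted = model.predict(A, D)["total"]
    train_r = float(
        np.corrcoef(fitted, truth.hybrid_values.reindex(fitted.index))[0, 1]
    )
    h2 = fit_diallel(train_pheno, crosses, panel, max_iter=max_iter).h2

    # year-2 regional assay: training hybrids plus new crosses of same lines
    rng = np.random.default_rng(seed + 10_000)
    tested = set(crosses.pairs)
    candidates = [
        (a, b)
        for a in panel.group_lines(1)
        for b in panel.group_lines(2)
        if tuple(sorted((a, b))) not in tested
    ]
    extra_idx = rng.choice(len(candidates), size=n_new_hybrids, replace=False)
    regional_crosses = CrossSet(
        list(crosses.pairs) + [candidates[i] for i in sorted(extra_idx)]
    )
    regional_trial = TrialSpec(n_environments=regional_environments, env_prefix="Y2E")
    regional_pheno, _ = simulate_trial(
        regional_crosses, regional_trial, v, "marker-truth", panel,
        seed=seed + 20_000, reuse_truth=truth,
    )

    ranked = predict_all_crosses(panel, model)
    ext = external_validate(
        ranked["total"], regional_pheno, fraction=selection_fraction
    )
    return ExternalExperimentResult(
        training_heritability=float(h2),
        training_fit_r=train_r,
        external_correlation=ext.correlation,
        external_r2_linear=ext.r2_linear,
        external_r2_quadratic=ext.r2_quadratic,
        correct_rate=ext.selection.correct_rate,
        wrong_rate=ext.selection.wrong_rate,
        n_overlap=ext.n_overlap,
    )
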