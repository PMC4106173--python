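"""Predicting tested and untested single crosses from fitted marker effects.

A fitted TEAM model assigns an effect to every training allele and allele
pair; any cross between panel lines — evaluated in the field or not — is
predicted by building its additive/dominance design rows against the
trained column indexes and summing the effects it carries:

    alpha_i = A_row . a        (lambda in {0, 1, 2} per allele)
    delta_i = D_row . d        (phi in {0, 1} per allele pair)

Allele pairs never realized in the training crosses have no estimated
dominance effect; they contribute the ridge prior mean of zero, and the
per-hybrid `dominance_coverage` column reports how much of the genome such
gaps affect.  Predictions are genetic values only (no fixed effects), so
rankings are invariant to environment means.
"""

from __future__ import annotations

import logging

import pandas as pd

from .matrices import AdditiveMatrix, DominanceMatrix, build_additive_matrix, build_dominance_matrix
from .panel import CrossSet, LinePanel, hybrid_id
from .team import TeamModel

logger = logging.getLogger(__name__)


def predict_hybrids(
    model: TeamModel,
    A_rows: AdditiveMatrix,
    D_rows: DominanceMatrix | None = None,
) -> pd.DataFrame:
    """Genetic values (alpha, delta, total) for explicit design rows.

    Hybrids whose dominance coverage is zero (no training pair at any
    marker) are still predicted from additive effects but flagged with a
    warning.
    """
    pred = model.predict(A_rows, D_rows)
    uncovered = pred.index[pred["dominance_coverage"].fillna(1.0) == 0.0]
    if len(uncovered):
        logger.warning(
            "%d hybrids have no trained dominance pair at any marker: %s",
            len(uncovered),
            list(uncovered[:5]),
        )
    return pred


def predict_all_crosses(
    panel: LinePanel,
    model: TeamModel,
    scheme: str = "between-groups",
) -> pd.DataFrame:
    """Predict and rank every admissible cross among the panel lines.

    Returns one row per candidate hybrid, sorted by descending total
    genetic value, with parents, additive/dominance components, a flag for
    crosses present in the training set, and dominance coverage.
    """
    if scheme == "between-groups":
        pairs = [(a, b) for a in panel.group_lines(1) for b in panel.group_lines(2)]
    elif scheme == "all-pairs":
        lines = panel.lines
        pairs = [
            (lines[i], lines[j])
            for i in range(len(lines))
            for j in range(i + 1, len(lines))
        ]
    else:
        raise ValueError(f"unknown crossing scheme {scheme!r}")
    crosses = CrossSet(pairs)
    A_rows = build_additive_matrix(panel, crosses, allele_index=model.allele_index_)
    D_rows = None
    if model.variant == "TEAM2":
        D_rows = build_dominance_matrix(panel, crosses, pair_index=model.pair_index_)
    pred = model.predict(A_rows, D_rows)
    parents = {hybrid_id(a, b): (a, b) for a, b in crosses}
    pred.insert(0, "parent1", [parents[h][0] for h in pred.index])
    pred.insert(1, "parent2", [parents[h][1] for h in pred.index])
    pred["trained"] = pred.index.isin(model.training_hybrids_)
    pred = pred.sort_values(["total", "parent1", "parent2"], ascending=[False, True, True])
    pred["rank"] = range(1, len(pred) + 1)
    return pred
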