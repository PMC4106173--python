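import numpy as np
import pandas as pd
import pytest

import teamcross as tc


@pytest.fixture(scope="session")
def small_world():
    """A small but non-trivial two-group world with marker ground truth.

    8+8 lines, 12 triallelic-to-hexallelic markers, 24 between-group
    crosses, 3 environments x 2 replicates; moderate noise so marker
    effects are estimable quickly.
    """
    panel = tc.simulate_line_panel(
        8, 8, tc.MarkerSpec(n_markers=12, mean_alleles=4, min_alleles=3, max_alleles=6), seed=5
    )
    crosses, _ = tc.simulate_cross_set(panel, 24, seed=5)
    trial = tc.TrialSpec(n_environments=3, n_replicates=2, block_size=8)
    variances = tc.GeneratingVariances(
        sigma2_gca1xE=0.02, sigma2_gca2xE=0.02, sigma2_scaxE=0.02, sigma2_residual=0.05
    )
    pheno, truth = tc.simulate_trial(
        crosses, trial, variances, "marker-truth", panel, seed=5
    )
    A = tc.build_additive_matrix(panel, crosses)
    D = tc.build_dominance_matrix(panel, crosses)
    return dict(
        panel=panel, crosses=crosses, trial=trial, variances=variances,
        pheno=pheno, truth=truth, A=A, D=D,
    )


@pytest.fixture(scope="session")
def study_scale_panel():
    """Panel at the replication scale: 27+24 lines, 79 SSR loci."""
    panel = tc.simulate_line_panel(27, 24, tc.MarkerSpec(), seed=11)
    crosses, _ = tc.simulate_cross_set(panel, 58, seed=11)
    return panel, crosses


@pytest.fixture(scope="session")
def team_fit(small_world):
    model = tc.TeamModel("TEAM2", max_iter=2000).fit(
        small_world["pheno"], small_world["A"], small_world["D"]
    )
    return model


def make_manual_panel(genotypes: dict, groups: dict) -> tc.LinePanel:
    """Panel from {line: {marker: allele}} and {line: group}."""
    frame = pd.DataFrame(genotypes).T
    return tc.LinePanel(frame, pd.Series(groups))
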