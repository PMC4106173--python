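"""Synthetic two-group maize hybrid trials with known ground truth.

No genotype or field data accompany the study design this package targets,
so every stage is exercised on simulated material that mirrors its
structure: 51 inbred lines in two heterotic groups (27 + 24), 79 SSR loci
averaging 8.05 alleles each, 58 between-group single crosses in an
incomplete partial diallel, and yield trials in 7 environments with 2
replicates laid out in incomplete blocks.  Generating variances default to
the magnitudes estimated in that study (GCA-group-1 0.055, GCA-group-2
0.077, SCA 0.063 t2.ha-2, genotype-by-environment interaction several times
the genetic variance).

Two truth modes are available:

* ``diallel-truth`` draws line combining abilities and cross-specific
  deviations directly — the data-generating model matches the two-group
  diallel analysis, so it is the right substrate for variance-component
  recovery experiments.
* ``marker-truth`` draws one additive effect per marker allele and one
  dominance effect per realized allele pair, builds hybrid genetic values
  through the additive/dominance design matrices, and is the right
  substrate for marker-model (TEAM) recovery and cross-validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel import CrossSet, LinePanel, hybrid_id


@dataclass(frozen=True)
class MarkerSpec:
    """How many loci to simulate and how polymorphic they are.

    Allele counts per locus are drawn as ``min + Binomial(max - min, p)``
    with ``p`` chosen so the expected count equals ``mean_alleles`` — a
    truncated discrete distribution matching the reported mean (8.05) and
    bounded away from monomorphism.
    """

    n_markers: int = 79
    mean_alleles: float = 8.05
    min_alleles: int = 2
    max_alleles: int = 20
    linkage_group_labels: tuple | None = None

    def __post_init__(self):
        if self.n_markers < 1:
            raise ValueError("n_markers must be >= 1")
        if not (1 <= self.min_alleles <= self.mean_alleles <= self.max_alleles):
            raise ValueError("need min_alleles <= mean_alleles <= max_alleles, all >= 1")
        if self.linkage_group_labels is not None and len(
            self.linkage_group_labels
        ) != self.n_markers:
            raise ValueError("one linkage-group label per marker required")

    def draw_allele_counts(self, rng: np.random.Generator) -> np.ndarray:
        span = self.max_alleles - self.min_alleles
        if span == 0:
            return np.full(self.n_markers, self.min_alleles, dtype=int)
        p = (self.mean_alleles - self.min_alleles) / span
        return self.min_alleles + rng.binomial(span, p, size=self.n_markers)


@dataclass(frozen=True)
class TrialSpec:
    """Multi-environment trial layout: replicates in incomplete blocks.

    Each replicate of each environment contains one plot per hybrid; the
    plots of a replicate are partitioned at random into incomplete blocks
    of `block_size` (last block possibly smaller).  Environment, replicate
    and block effects are fixed, drawn once per simulation with the given
    spreads (t.ha-1).
    """

    n_environments: int = 7
    n_replicates: int = 2
    block_size: int = 10
    env_sd: float = 1.0
    rep_sd: float = 0.25
    block_sd: float = 0.25
    env_prefix: str = "E"

    def __post_init__(self):
        if min(self.n_environments, self.n_replicates, self.block_size) < 1:
            raise ValueError("environments, replicates and block size must be >= 1")
        if min(self.env_sd, self.rep_sd, self.block_sd) < 0:
            raise ValueError("effect spreads must be non-negative")


@dataclass(frozen=True)
class GeneratingVariances:
    """Generating variance components, all in t2.ha-2 (mean in t.ha-1)."""

    sigma2_gca1: float = 0.055
    sigma2_gca2: float = 0.077
    sigma2_sca: float = 0.063
    sigma2_gca1xE: float = 0.225
    sigma2_gca2xE: float = 0.225
    sigma2_scaxE: float = 0.23
    sigma2_residual: float = 0.136
    grand_mean: float = 9.0

    def __post_init__(self):
        for name in (
            "sigma2_gca1",
            "sigma2_gca2",
            "sigma2_sca",
            "sigma2_gca1xE",
            "sigma2_gca2xE",
            "sigma2_scaxE",
            "sigma2_residual",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def total_genetic(self) -> float:
        return self.sigma2_gca1 + self.sigma2_gca2 + self.sigma2_sca

    @property
    def total_gxe(self) -> float:
        return self.sigma2_gca1xE + self.sigma2_gca2xE + self.sigma2_scaxE


def replication_preset() -> GeneratingVariances:
    """The replication preset: variance magnitudes of the source study.

    GCA variances 0.055 and 0.077, SCA 0.063; the reported combining-
    ability-by-environment totals (0.45 for the two GCA terms jointly,
    0.23 for SCA-by-environment) are split as 0.225 + 0.225 + 0.23; the
    residual 0.136 makes the interaction total five times the residual.
    """
    return GeneratingVariances()


@dataclass
class TruthRecord:
    """Ground truth behind one simulated trial (for recovery tests)."""

    mode: str
    seed: int
    variances: GeneratingVariances
    gca: pd.Series | None = None  # per line
    sca: pd.Series | None = None  # per hybrid
    additive_effects: pd.Series | None = None  # per (marker, allele)
    dominance_effects: pd.Series | None = None  # per (marker, allele pair)
    hybrid_values: pd.Series = field(default_factory=pd.Series)
    env_effects: pd.Series | None = None
    rep_effects: pd.Series | None = None
    block_effects: pd.Series | None = None


def simulate_line_panel(
    n_lines_group1: int,
    n_lines_group2: int,
    marker_spec: MarkerSpec | None = None,
    seed: int = 0,
) -> LinePanel:
    """Simulate homozygous line genotypes at multiallelic loci.

    Each line draws one allele per locus, uniformly from that locus's
    allele pool (the allele-frequency spectrum across lines is not reported
    for the real panel; uniform is the configurable default).
    """
    if n_lines_group1 < 1 or n_lines_group2 < 1:
        raise ValueError("each heterotic group needs at least one line")
    spec = marker_spec or MarkerSpec()
    rng = np.random.default_rng(seed)
    n_lines = n_lines_group1 + n_lines_group2
    lines = [f"L{i + 1:02d}" for i in range(n_lines)]
    markers = [f"M{j + 1:03d}" for j in range(spec.n_markers)]
    counts = spec.draw_allele_counts(rng)
    data = {}
    for j, marker in enumerate(markers):
        pool = [f"a{t + 1}" for t in range(counts[j])]
        data[marker] = rng.choice(pool, size=n_lines)
    genotypes = pd.DataFrame(data, index=lines)
    groups = pd.Series(
        [1] * n_lines_group1 + [2] * n_lines_group2, index=lines, dtype=int
    )
    return LinePanel(genotypes, groups)


def simulate_cross_set(
    panel: LinePanel,
    n_crosses: int,
    scheme: str = "between-groups-partial",
    seed: int = 0,
) -> tuple[CrossSet, pd.Series]:
    """Sample a partial set of crosses and report per-line connectivity.

    ``between-groups-partial`` samples unique group1 × group2 pairs (the
    partial-diallel design between heterotic groups); ``all-pairs`` samples
    from every unordered pair of distinct lines.
    """
    rng = np.random.default_rng(seed)
    if scheme == "between-groups-partial":
        g1, g2 = panel.group_lines(1), panel.group_lines(2)
        admissible = [(a, b) for a in g1 for b in g2]
    elif scheme == "all-pairs":
        lines = panel.lines
        admissible = [
            (lines[i], lines[j])
            for i in range(len(lines))
            for j in range(i + 1, len(lines))
        ]
    else:
        raise ValueError(f"unknown crossing scheme {scheme!r}")
    if n_crosses > len(admissible):
        raise ValueError(
            f"{n_crosses} crosses requested but only {len(admissible)} admissible pairs"
        )
    idx = rng.choice(len(admissible), size=n_crosses, replace=False)
    crosses = CrossSet([admissible[i] for i in sorted(idx)])
    return crosses, crosses.connectivity()


def _field_layout(
    crosses: CrossSet, trial: TrialSpec, rng: np.random.Generator
) -> pd.DataFrame:
    """One plot per hybrid per replicate per environment, blocked at random."""
    hybrids = crosses.hybrids
    rows = []
    for e in range(trial.n_environments):
        env = f"{trial.env_prefix}{e + 1}"
        for r in range(trial.n_replicates):
            rep = f"R{r + 1}"
            order = rng.permutation(len(hybrids))
            for pos, hy_idx in enumerate(order):
                rows.append(
                    {
                        "hybrid": hybrids[hy_idx],
                        "environment": env,
                        "replicate": rep,
                        "block": f"B{pos // trial.block_size + 1}",
                    }
                )
    return pd.DataFrame(rows)


def simulate_trial(
    crosses: CrossSet,
    trial: TrialSpec,
    variances: GeneratingVariances,
    truth_mode: str = "diallel-truth",
    panel: LinePanel | None = None,
    seed: int = 0,
    additive_fraction: float | None = None,
    reuse_truth: TruthRecord | None = None,
    effect_scale: str = "per-hybrid",
) -> tuple[pd.DataFrame, TruthRecord]:
    """Simulate plot-level grain yields for a set of crosses.

    Every plot's yield is the grand mean plus fixed environment, replicate
    and block effects, the hybrid's genetic value, a genotype-by-
    environment draw, and an independent residual — each drawn with its
    generating variance.  ``diallel-truth`` composes genetic values as
    GCA(parent1) + GCA(parent2) + SCA(cross); ``marker-truth`` composes
    them from per-allele additive and per-allele-pair dominance effects
    whose column variances are scaled so the expected total genetic
    variance matches the preset (split ``additive_fraction`` to additive;
    default = the preset's GCA share of genetic variance).

    Passing a previous `TruthRecord` as `reuse_truth` keeps the genetic
    values fixed and redraws only environments, field layout, interaction
    and residual terms — emulating the same hybrids grown in a different
    year/region (external-validation trials).
    """
    if panel is None:
        raise ValueError("a line panel is required to resolve cross parents")
    crosses.validate_against(panel)
    if truth_mode not in ("diallel-truth", "marker-truth"):
        raise ValueError(f"unknown truth mode {truth_mode!r}")
    rng = np.random.default_rng(seed)
    v = variances

    layout = _field_layout(crosses, trial, rng)
    hybrids = crosses.hybrids
    parents = {hybrid_id(a, b): (a, b) for a, b in crosses}

    env_levels = sorted(layout["environment"].unique())
    env_eff = pd.Series(rng.normal(0.0, trial.env_sd, len(env_levels)), index=env_levels)
    rep_keys = sorted((layout["environment"] + "/" + layout["replicate"]).unique())
    rep_eff = pd.Series(rng.normal(0.0, trial.rep_sd, len(rep_keys)), index=rep_keys)
    blk_keys = sorted(
        (
            layout["environment"] + "/" + layout["replicate"] + "/" + layout["block"]
        ).unique()
    )
    blk_eff = pd.Series(rng.normal(0.0, trial.block_sd, len(blk_keys)), index=blk_keys)

    record = TruthRecord(
        mode=truth_mode,
        seed=seed,
        variances=v,
        env_effects=env_eff,
        rep_effects=rep_eff,
        block_effects=blk_eff,
    )

    if truth_mode == "diallel-truth":
        g1, g2 = panel.group_lines(1), panel.group_lines(2)
        if reuse_truth is not None:
            if reuse_truth.gca is None or reuse_truth.sca is None:
                raise ValueError("reuse_truth lacks diallel-truth components")
            gca = reuse_truth.gca.copy()
            sca = reuse_truth.sca.reindex(hybrids)
            new = sca.index[sca.isna()]  # crosses absent from the first trial
            sca[new] = rng.normal(0.0, np.sqrt(v.sigma2_sca), len(new))
        else:
            gca = pd.Series(0.0, index=panel.lines)
            gca[g1] = rng.normal(0.0, np.sqrt(v.sigma2_gca1), len(g1))
            gca[g2] = rng.normal(0.0, np.sqrt(v.sigma2_gca2), len(g2))
            sca = pd.Series(
                rng.normal(0.0, np.sqrt(v.sigma2_sca), len(hybrids)), index=hybrids
            )
        values = pd.Series(
            [gca[parents[h][0]] + gca[parents[h][1]] + sca[h] for h in hybrids],
            index=hybrids,
        )
        record.gca, record.sca, record.hybrid_values = gca, sca, values
        # per-(line, env) and per-(cross, env) interaction draws
        ixn1 = rng.normal(0.0, np.sqrt(v.sigma2_gca1xE), (len(g1), len(env_levels)))
        ixn2 = rng.normal(0.0, np.sqrt(v.sigma2_gca2xE), (len(g2), len(env_levels)))
        ixn_s = rng.normal(0.0, np.sqrt(v.sigma2_scaxE), (len(hybrids), len(env_levels)))
        i1 = pd.DataFrame(ixn1, index=g1, columns=env_levels)
        i2 = pd.DataFrame(ixn2, index=g2, columns=env_levels)
        iw = pd.DataFrame(ixn_s, index=hybrids, columns=env_levels)

        def gxe_of(h: str, env: str) -> float:
            a, b = parents[h]
            pa, pb = (a, b) if panel.groups[a] == 1 else (b, a)
            return i1.at[pa, env] + i2.at[pb, env] + iw.at[h, env]

    else:  # marker-truth
        from .matrices import build_additive_matrix, build_dominance_matrix

        A = build_additive_matrix(panel, crosses)
        D = build_dominance_matrix(panel, crosses)
        total = v.total_genetic
        f_add = (
            additive_fraction
            if additive_fraction is not None
            else ((v.sigma2_gca1 + v.sigma2_gca2) / total if total > 0 else 0.5)
        )
        n, k = A.shape[1], D.shape[1]
        # one common effect variance per column.  "per-hybrid" scales the
        # column variances by the average squared row loads so the realized
        # per-hybrid genetic variance matches `total` (and hence the
        # heritability the preset implies); "index" uses the
        # n*s2_a + k*s2_d = total convention of the variance-recovery
        # formula, which spreads `total` over all columns and yields a much
        # smaller per-hybrid variance.
        if effect_scale == "per-hybrid":
            load_a = float(np.mean(np.sum(A.values.astype(float) ** 2, axis=1)))
            load_d = float(np.mean(np.sum(D.values.astype(float) ** 2, axis=1)))
        elif effect_scale == "index":
            load_a, load_d = float(n), float(k)
        else:
            raise ValueError(f"unknown effect_scale {effect_scale!r}")
        s2_a = f_add * total / load_a if load_a else 0.0
        s2_d = (1.0 - f_add) * total / load_d if load_d else 0.0
        if reuse_truth is not None:
            if reuse_truth.additive_effects is None:
                raise ValueError("reuse_truth lacks marker-truth effects")
            a_eff = reuse_truth.additive_effects.reindex(A.columns)
            a_eff[a_eff.isna()] = rng.normal(
                0.0, np.sqrt(s2_a), int(a_eff.isna().sum())
            )
            d_eff = reuse_truth.dominance_effects.reindex(D.columns)
            d_eff[d_eff.isna()] = rng.normal(
                0.0, np.sqrt(s2_d), int(d_eff.isna().sum())
            )
        else:
            a_eff = pd.Series(rng.normal(0.0, np.sqrt(s2_a), n), index=A.columns)
            d_eff = pd.Series(rng.normal(0.0, np.sqrt(s2_d), k), index=D.columns)
        alpha = A.values @ a_eff.to_numpy()
        delta = D.values @ d_eff.to_numpy()
        values = pd.Series(alpha + delta, index=hybrids)
        record.additive_effects, record.dominance_effects = a_eff, d_eff
        record.hybrid_values = values
        gxe_sd = np.sqrt(v.total_gxe)
        iw = pd.DataFrame(
            rng.normal(0.0, gxe_sd, (len(hybrids), len(env_levels))),
            index=hybrids,
            columns=env_levels,
        )

        def gxe_of(h: str, env: str) -> float:
            return iw.at[h, env]

    resid = rng.normal(0.0, np.sqrt(v.sigma2_residual), len(layout))
    yields = np.empty(len(layout))
    for i, row in enumerate(layout.itertuples(index=False)):
        h, env = row.hybrid, row.environment
        rep_key = f"{env}/{row.replicate}"
        blk_key = f"{rep_key}/{row.block}"
        yields[i] = (
            v.grand_mean
            + env_eff[env]
            + rep_eff[rep_key]
            + blk_eff[blk_key]
            + record.hybrid_values[h]
            + gxe_of(h, env)
            + resid[i]
        )
    pheno = layout.copy()
    pheno["yield"] = yields
    return pheno, record
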