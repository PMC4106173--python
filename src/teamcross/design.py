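"""Design-matrix construction from plot-level phenotype tables.

A phenotype table has one row per field plot with columns ``hybrid``,
``environment``, ``replicate``, ``block`` and ``yield`` (grain yield in
t.ha-1).  Replicates are nested in environments and incomplete blocks are
nested in replicates.  Environments, replicates and blocks enter the models
as fixed effects, ordered environment -> replicate -> block before the
greedy full-rank reduction, so collinear trailing block columns are the
ones dropped.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .mme import full_rank_columns

PHENO_COLUMNS = ["hybrid", "environment", "replicate", "block", "yield"]


def check_phenotypes(pheno: pd.DataFrame) -> pd.DataFrame:
    """Validate and normalize a plot-level phenotype table."""
    missing = [c for c in PHENO_COLUMNS if c not in pheno.columns]
    if missing:
        raise ValueError(f"phenotype table lacks columns: {missing}")
    out = pheno.loc[:, PHENO_COLUMNS].copy()
    for c in PHENO_COLUMNS[:-1]:
        out[c] = out[c].astype(str)
    out["yield"] = pd.to_numeric(out["yield"], errors="raise").astype(float)
    if not np.all(np.isfinite(out["yield"])):
        raise ValueError("non-finite yields in phenotype table")
    if len(out) == 0:
        raise ValueError("empty phenotype table")
    return out


def incidence(codes: np.ndarray, n_levels: int) -> sp.csr_matrix:
    """Sparse one-hot incidence matrix from integer level codes (-1 = none)."""
    codes = np.asarray(codes)
    rows = np.flatnonzero(codes >= 0)
    mat = sp.csr_matrix(
        (np.ones(rows.size), (rows, codes[rows])),
        shape=(codes.size, n_levels),
    )
    return mat


def factor(values: pd.Series) -> tuple[np.ndarray, list[str]]:
    """Integer codes and sorted level labels for a categorical column."""
    levels = sorted(pd.unique(values.astype(str)))
    lookup = {v: i for i, v in enumerate(levels)}
    codes = values.astype(str).map(lookup).to_numpy()
    return codes, levels


def fixed_effects_design(pheno: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Full-rank fixed design: intercept, environment, replicate, block.

    Replicates are coded within environment and blocks within
    (environment, replicate); every factor uses full dummy coding and the
    greedy reduction keeps a maximal independent subset in the order
    intercept -> environment -> replicate -> block.
    """
    pheno = check_phenotypes(pheno)
    n = len(pheno)
    cols: list[np.ndarray] = [np.ones(n)]
    names: list[str] = ["intercept"]

    env = pheno["environment"]
    rep = env + "/" + pheno["replicate"]
    blk = rep + "/" + pheno["block"]
    for label, series in (("env", env), ("rep", rep), ("block", blk)):
        codes, levels = factor(series)
        if len(levels) < 2:
            continue
        dummies = incidence(codes, len(levels)).toarray()
        for j, lev in enumerate(levels):
            cols.append(dummies[:, j])
            names.append(f"{label}[{lev}]")
    X = np.column_stack(cols)
    keep = full_rank_columns(X)
    return X[:, keep], [names[j] for j in keep]


def design_from_columns(pheno: pd.DataFrame, x_columns: list[str]) -> np.ndarray:
    """Rebuild fixed-design rows for new plots against trained column labels.

    Used to adjust held-out observations with fixed effects estimated on
    training plots: columns are matched by label ("env[E1]",
    "rep[E1/R1]", "block[E1/R1/B2]"); levels absent from the trained
    design contribute zero.
    """
    pheno = check_phenotypes(pheno)
    env = pheno["environment"]
    rep = env + "/" + pheno["replicate"]
    blk = rep + "/" + pheno["block"]
    series = {"env": env, "rep": rep, "block": blk}
    X = np.zeros((len(pheno), len(x_columns)))
    for j, name in enumerate(x_columns):
        if name == "intercept":
            X[:, j] = 1.0
            continue
        label, _, rest = name.partition("[")
        level = rest[:-1]
        if label not in series:
            raise ValueError(f"unrecognized design column {name!r}")
        X[:, j] = (series[label] == level).to_numpy(dtype=float)
    return X


def hybrid_incidence(
    pheno: pd.DataFrame, hybrids: list[str]
) -> tuple[sp.csr_matrix, np.ndarray]:
    """Plot -> hybrid incidence aligned to an explicit hybrid ordering."""
    lookup = {h: i for i, h in enumerate(hybrids)}
    unknown = sorted(set(pheno["hybrid"]) - set(hybrids))
    if unknown:
        raise ValueError(f"phenotype rows reference unknown hybrids: {unknown[:5]}")
    codes = pheno["hybrid"].map(lookup).to_numpy()
    return incidence(codes, len(hybrids)), codes


def adjusted_hybrid_means(
    pheno: pd.DataFrame, beta: np.ndarray | None = None, x_design=None
) -> pd.Series:
    """Fixed-effect-adjusted hybrid means.

    Subtracts estimated environment/replicate/block effects from each plot
    and averages per hybrid.  If `beta`/`x_design` (a design matrix and
    solution from a previous fit on other data) are not supplied, the fixed
    effects are estimated here by ordinary least squares with hybrid
    dummies appended (so hybrid contrasts are not absorbed into blocks).
    """
    pheno = check_phenotypes(pheno)
    if beta is None:
        X, names = fixed_effects_design(pheno)
        codes, hybrids = factor(pheno["hybrid"])
        H = incidence(codes, len(hybrids)).toarray()
        full = np.column_stack([X, H])
        keep = full_rank_columns(full)
        sol, *_ = np.linalg.lstsq(full[:, keep], pheno["yield"].to_numpy(), rcond=None)
        coef = np.zeros(full.shape[1])
        coef[keep] = sol
        fixed_part = X @ coef[: X.shape[1]]
    else:
        fixed_part = np.asarray(x_design) @ np.asarray(beta)
        if fixed_part.shape[0] != len(pheno):
            raise ValueError("x_design rows do not match phenotype table")
    adj = pheno["yield"].to_numpy() - fixed_part
    return pd.Series(adj).groupby(pheno["hybrid"].to_numpy()).mean().rename("adjusted_mean")
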