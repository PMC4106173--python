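"""Hybrid-level marker design matrices and the genetic-distance baseline.

With fully homozygous parents, a single-cross hybrid's genotype at a locus
is the unordered pair of its parents' alleles.  Two design matrices encode
this for ridge-type marker models:

* the **additive matrix** has one column per (marker, allele) key and
  entries lambda in {0, 1, 2}: the number of parents carrying that allele
  (2 when both parents share it, 1 when exactly one does);
* the **dominance matrix** has one column per (marker, unordered allele
  pair) realized in the cross set and entries phi in {0, 1}: per marker
  exactly the column keyed by the hybrid's parental allele pair is 1 (the
  homozygous pair when the parents share the allele).

The classical alternative predictor is the Jaccard genetic distance
``1 - s_ij`` between parental allele-presence profiles, assessed against a
phenotypic distance with a permutation Mantel test.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations
from math import factorial

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .panel import CrossSet, LinePanel

AlleleKey = tuple  # (marker, allele)
PairKey = tuple  # (marker, (allele_lo, allele_hi))


def enumerate_alleles(panel: LinePanel) -> list[AlleleKey]:
    """Ordered (marker, allele) keys observed in the panel.

    Ordering is deterministic: panel marker order, then allele identifier
    ascending.  The length of this index is the additive dimension n.
    """
    keys: list[AlleleKey] = []
    for marker in panel.markers:
        col = panel.genotypes[marker]
        keys.extend((marker, allele) for allele in sorted(col.dropna().unique()))
    return keys


@dataclass
class AdditiveMatrix:
    """Hybrids × (marker, allele) design with entries in {0, 1, 2}."""

    hybrids: list[str]
    columns: list[AlleleKey]
    values: np.ndarray
    coverage: pd.Series | None = None  # genotyped-marker coverage when aligned

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        cols = [f"{m}:{a}" for m, a in self.columns]
        return pd.DataFrame(self.values, index=self.hybrids, columns=cols)

    def row(self, hybrid: str) -> np.ndarray:
        return self.values[self.hybrids.index(hybrid)]


@dataclass
class DominanceMatrix:
    """Hybrids × (marker, allele-pair) one-hot-per-marker design."""

    hybrids: list[str]
    columns: list[PairKey]
    values: np.ndarray
    coverage: pd.Series | None = None  # fraction of markers whose pair is indexed

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        cols = [f"{m}:{p[0]}/{p[1]}" for m, p in self.columns]
        return pd.DataFrame(self.values, index=self.hybrids, columns=cols)

    def row(self, hybrid: str) -> np.ndarray:
        return self.values[self.hybrids.index(hybrid)]


def build_additive_matrix(
    panel: LinePanel,
    crosses: CrossSet,
    allele_index: list[AlleleKey] | None = None,
) -> AdditiveMatrix:
    """Additive design: per hybrid, count of parents carrying each allele.

    A marker missing in either parent contributes nothing to that hybrid's
    row.  When `allele_index` is supplied (prediction against a trained
    model), rows are aligned to it and alleles absent from the index are
    skipped; `coverage` then reports, per hybrid, the fraction of its
    genotyped markers fully represented in the index.
    """
    crosses.validate_against(panel)
    index = allele_index if allele_index is not None else enumerate_alleles(panel)
    lookup = {key: j for j, key in enumerate(index)}
    hybrids = crosses.hybrids
    vals = np.zeros((len(hybrids), len(index)), dtype=np.int8)
    covered = np.zeros(len(hybrids))
    genotyped = np.zeros(len(hybrids))
    for i, (a, b) in enumerate(crosses):
        for marker in panel.markers:
            al_a, al_b = panel.allele(a, marker), panel.allele(b, marker)
            if pd.isna(al_a) or pd.isna(al_b):
                continue
            genotyped[i] += 1
            hit = 0
            for allele in (al_a, al_b):
                j = lookup.get((marker, allele))
                if j is not None:
                    vals[i, j] += 1
                    hit += 1
            if hit == 2:
                covered[i] += 1
    with np.errstate(invalid="ignore"):
        cov = np.where(genotyped > 0, covered / np.maximum(genotyped, 1), np.nan)
    return AdditiveMatrix(
        hybrids=hybrids,
        columns=list(index),
        values=vals,
        coverage=pd.Series(cov, index=hybrids, name="additive_coverage"),
    )


def build_dominance_matrix(
    panel: LinePanel,
    crosses: CrossSet,
    pair_index: list[PairKey] | None = None,
) -> DominanceMatrix:
    """Dominance design: one-hot parental allele pair per marker.

    Columns are created only for allele pairs realized in the given cross
    set (so the dominance dimension k is cross-set dependent) unless an
    explicit `pair_index` from a trained model is supplied, in which case
    unseen pairs contribute nothing and `coverage` reports the fraction of
    genotyped markers whose realized pair is in the index.
    """
    crosses.validate_against(panel)
    hybrids = crosses.hybrids

    def realized_pair(a_allele, b_allele) -> tuple:
        lo, hi = sorted((a_allele, b_allele))
        return (lo, hi)

    if pair_index is None:
        seen: dict[PairKey, None] = {}
        for a, b in crosses:
            for marker in panel.markers:
                al_a, al_b = panel.allele(a, marker), panel.allele(b, marker)
                if pd.isna(al_a) or pd.isna(al_b):
                    continue
                seen[(marker, realized_pair(al_a, al_b))] = None
        marker_order = {m: j for j, m in enumerate(panel.markers)}
        index = sorted(seen, key=lambda key: (marker_order[key[0]], key[1]))
    else:
        index = list(pair_index)
    lookup = {key: j for j, key in enumerate(index)}

    vals = np.zeros((len(hybrids), len(index)), dtype=np.int8)
    covered = np.zeros(len(hybrids))
    genotyped = np.zeros(len(hybrids))
    for i, (a, b) in enumerate(crosses):
        for marker in panel.markers:
            al_a, al_b = panel.allele(a, marker), panel.allele(b, marker)
            if pd.isna(al_a) or pd.isna(al_b):
                continue
            genotyped[i] += 1
            j = lookup.get((marker, realized_pair(al_a, al_b)))
            if j is not None:
                vals[i, j] = 1
                covered[i] += 1
    with np.errstate(invalid="ignore"):
        cov = np.where(genotyped > 0, covered / np.maximum(genotyped, 1), np.nan)
    return DominanceMatrix(
        hybrids=hybrids,
        columns=index,
        values=vals,
        coverage=pd.Series(cov, index=hybrids, name="dominance_coverage"),
    )


def jaccard_distance_matrix(panel: LinePanel) -> pd.DataFrame:
    """Line × line genetic distances 1 - s_ij (Jaccard similarity s_ij).

    s_ij = |alleles shared| / |alleles in either line| over the binary
    allele-presence profiles.
    """
    presence = panel.allele_presence().to_numpy(dtype=bool)
    empty = ~presence.any(axis=1)
    if empty.any():
        bad = [panel.lines[i] for i in np.flatnonzero(empty)]
        raise ValueError(f"lines with no genotyped markers: {bad}")
    dist = squareform(pdist(presence, metric="jaccard"))
    return pd.DataFrame(dist, index=panel.lines, columns=panel.lines)


def _check_distance(mat, name: str) -> np.ndarray:
    arr = np.asarray(mat, dtype=float)
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise ValueError(f"{name} must be a square matrix")
    if not np.allclose(arr, arr.T):
        raise ValueError(f"{name} must be symmetric")
    if not np.allclose(np.diag(arr), 0.0):
        raise ValueError(f"{name} must have a zero diagonal")
    return arr


def mantel_test(
    d1, d2, n_permutations: int = 999, seed: int = 0
) -> tuple[float, float]:
    """Mantel correlation between two distance matrices with permutation p.

    r is the Pearson correlation of the upper off-diagonal triangles; the
    two-sided p-value is the proportion of simultaneous row/column
    permutations of `d2` whose |r| is at least the observed |r|, with the
    identity permutation included.  When the full permutation group is no
    larger than `n_permutations` the enumeration is exhaustive (exact p);
    otherwise permutations are sampled.
    """
    a = _check_distance(d1, "d1")
    b = _check_distance(d2, "d2")
    if a.shape != b.shape:
        raise ValueError("distance matrices are not conformable")
    n = a.shape[0]
    iu = np.triu_indices(n, k=1)
    x = a[iu]
    y = b[iu]
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("constant distance matrix: Mantel correlation undefined")

    def corr(vec_y: np.ndarray) -> float:
        return float(np.corrcoef(x, vec_y)[0, 1])

    r_obs = corr(y)
    total = factorial(n)
    hits = 0
    if total <= n_permutations:
        count = total
        for perm in permutations(range(n)):
            bp = b[np.ix_(perm, perm)]
            if abs(corr(bp[iu])) >= abs(r_obs) - 1e-12:
                hits += 1
        p = hits / count
    else:
        rng = np.random.default_rng(seed)
        hits = 1  # identity permutation
        for _ in range(n_permutations):
            perm = rng.permutation(n)
            bp = b[np.ix_(perm, perm)]
            if abs(corr(bp[iu])) >= abs(r_obs) - 1e-12:
                hits += 1
        p = hits / (n_permutations + 1)
    return r_obs, p
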