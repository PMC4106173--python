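"""Containers for inbred-line marker panels and single-cross sets.

The experimental material modelled here is a two-heterotic-group maize
breeding panel: homozygous inbred lines genotyped at multiallelic SSR
(microsatellite) loci, crossed in a partial diallel to produce single-cross
hybrids.  Because the lines are fully homozygous, each line carries exactly
one allele per locus and a hybrid's genotype at a locus is fully determined
by its two parents' alleles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

HYBRID_SEP = "×"  # "×" — canonical separator in hybrid identifiers


def hybrid_id(parent1: str, parent2: str) -> str:
    """Canonical hybrid identifier: lexicographically smaller parent first."""
    a, b = sorted((str(parent1), str(parent2)))
    return f"{a}{HYBRID_SEP}{b}"


def split_hybrid_id(hybrid: str) -> tuple[str, str]:
    for sep in (HYBRID_SEP, "x"):
        if sep in hybrid:
            a, _, b = hybrid.partition(sep)
            if a and b:
                return a, b
    raise ValueError(f"malformed hybrid identifier: {hybrid!r}")


class LinePanel:
    """Inbred lines × SSR markers, one allele per (line, marker) cell.

    Parameters
    ----------
    genotypes : DataFrame
        Wide table, index = line identifiers, columns = marker names,
        values = allele identifiers (strings, scoped per marker).  NaN
        marks a missing genotype.
    groups : Series
        Heterotic-group label (1 or 2) per line, indexed like `genotypes`.
    """

    def __init__(self, genotypes: pd.DataFrame, groups: pd.Series):
        if genotypes.shape[0] == 0 or genotypes.shape[1] == 0:
            raise ValueError("panel must contain at least one line and one marker")
        groups = groups.reindex(genotypes.index)
        if groups.isna().any():
            missing = list(genotypes.index[groups.isna()])
            raise ValueError(f"lines without a group label: {missing}")
        if not set(groups.unique()) <= {1, 2}:
            raise ValueError("group labels must be 1 or 2")
        self.genotypes = genotypes.astype("object")
        self.groups = groups.astype(int)

    # -- basic accessors ---------------------------------------------------
    @property
    def lines(self) -> list[str]:
        return list(self.genotypes.index)

    @property
    def markers(self) -> list[str]:
        return list(self.genotypes.columns)

    @property
    def n_lines(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_markers(self) -> int:
        return self.genotypes.shape[1]

    def group_lines(self, group: int) -> list[str]:
        return list(self.groups.index[self.groups == group])

    def allele(self, line: str, marker: str):
        """Allele carried by `line` at `marker` (NaN if missing)."""
        return self.genotypes.at[line, marker]

    def is_missing(self, line: str, marker: str) -> bool:
        return pd.isna(self.genotypes.at[line, marker])

    # -- derived views -----------------------------------------------------
    def allele_presence(self) -> pd.DataFrame:
        """Binary line × (marker, allele) presence profile.

        Columns are a MultiIndex of (marker, allele) keys ordered by marker
        then allele identifier; entries are 1 where the line carries that
        allele.  Homozygous lines carry exactly one allele per genotyped
        locus, so each row has one 1 per non-missing marker.
        """
        keys = []
        cols = {}
        for marker in self.markers:
            col = self.genotypes[marker]
            for allele in sorted(col.dropna().unique()):
                keys.append((marker, allele))
                cols[(marker, allele)] = (col == allele).astype(np.int8).to_numpy()
        frame = pd.DataFrame(cols, index=self.genotypes.index)
        frame.columns = pd.MultiIndex.from_tuples(keys, names=["marker", "allele"])
        return frame

    def __repr__(self) -> str:  # pragma: no cover
        n1 = int((self.groups == 1).sum())
        n2 = int((self.groups == 2).sum())
        return (
            f"LinePanel({self.n_lines} lines [{n1}+{n2}], "
            f"{self.n_markers} markers)"
        )


@dataclass
class CrossSet:
    """An ordered collection of unique single crosses (unordered line pairs)."""

    pairs: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self):
        canon = [tuple(sorted((str(a), str(b)))) for a, b in self.pairs]
        if len(set(canon)) != len(canon):
            raise ValueError("duplicate crosses in cross set")
        for a, b in canon:
            if a == b:
                raise ValueError(f"self-cross not allowed in a cross set: {a}")
        self.pairs = canon

    @property
    def hybrids(self) -> list[str]:
        return [hybrid_id(a, b) for a, b in self.pairs]

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        return iter(self.pairs)

    def validate_against(self, panel: LinePanel) -> None:
        known = set(panel.lines)
        for a, b in self.pairs:
            if a not in known or b not in known:
                raise ValueError(f"cross ({a}, {b}) references lines absent from panel")

    def parents_by_group(self, panel: LinePanel) -> pd.DataFrame:
        """Table hybrid → (group-1 parent, group-2 parent).

        Raises if any cross is not a between-group pair; used by the
        two-group combining-ability model, which needs each hybrid to have
        exactly one parent per heterotic group.
        """
        rows = []
        for a, b in self.pairs:
            ga, gb = panel.groups[a], panel.groups[b]
            if {ga, gb} != {1, 2}:
                raise ValueError(
                    f"cross ({a}, {b}) is not a group1×group2 pair (groups {ga}, {gb})"
                )
            p1, p2 = (a, b) if ga == 1 else (b, a)
            rows.append((hybrid_id(a, b), p1, p2))
        return pd.DataFrame(rows, columns=["hybrid", "parent1", "parent2"]).set_index(
            "hybrid"
        )

    def connectivity(self) -> pd.Series:
        """Number of crosses each line participates in."""
        counts: dict[str, int] = {}
        for a, b in self.pairs:
            counts[a] = counts.get(a, 0) + 1
            counts[b] = counts.get(b, 0) + 1
        return pd.Series(counts, name="n_crosses").sort_index()
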