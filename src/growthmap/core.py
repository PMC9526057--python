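"""Core data containers shared across the mapping pipeline.

The mapping substrate is a biallelic, fully homozygous genotype matrix for a
panel of recombinant inbred lines derived from the N2 and CB4856 strains of
*C. elegans*, together with a genetic map placing each marker on a chromosome
at a physical (bp) and genetic (cM) position.

Allele coding convention used for all arithmetic: N2 -> -1, CB4856 -> +1, so a
positive effect size means the CB4856 allele increases the trait.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: The two parental alleles of the cross.
ALLELES = ("N2", "CB4856")

#: Numeric coding used everywhere arithmetic is done on genotypes.
ALLELE_CODE = {"N2": -1.0, "CB4856": 1.0}


class GeneticMap:
    """Ordered marker positions on chromosomes.

    Wraps a DataFrame with columns ``marker``, ``chrom``, ``bp``, ``cM``,
    sorted by (chromosome, bp). Within each chromosome both bp and cM must be
    strictly increasing and there must be at least two markers.
    """

    COLUMNS = ["marker", "chrom", "bp", "cM"]

    def __init__(self, table: pd.DataFrame):
        missing = set(self.COLUMNS) - set(table.columns)
        if missing:
            raise ValueError(f"genetic map missing columns: {sorted(missing)}")
        table = table[self.COLUMNS].copy()
        if table["marker"].duplicated().any():
            dup = table.loc[table["marker"].duplicated(), "marker"].iloc[0]
            raise ValueError(f"duplicate marker id in map: {dup!r}")
        # preserve first-appearance chromosome order (I..V, X, not lexical)
        chrom_order = {c: i for i, c in enumerate(table["chrom"].drop_duplicates())}
        table = table.sort_values(
            ["chrom", "bp"], key=lambda s: s.map(chrom_order) if s.name == "chrom" else s
        ).reset_index(drop=True)
        for chrom, grp in table.groupby("chrom", sort=False):
            if len(grp) < 2:
                raise ValueError(f"chromosome {chrom} has fewer than 2 markers")
            for col in ("bp", "cM"):
                if not np.all(np.diff(grp[col].to_numpy()) > 0):
                    raise ValueError(f"{col} not strictly increasing on chromosome {chrom}")
        if (table["cM"] < 0).any():
            raise ValueError("negative cM position")
        self.table = table

    @property
    def markers(self) -> pd.Index:
        return pd.Index(self.table["marker"])

    @property
    def chromosomes(self) -> list:
        return list(self.table["chrom"].drop_duplicates())

    def __len__(self) -> int:
        return len(self.table)

    def row(self, marker: str) -> pd.Series:
        hit = self.table[self.table["marker"] == marker]
        if hit.empty:
            raise KeyError(f"marker {marker!r} not in map")
        return hit.iloc[0]

    def markers_in(self, chrom, left_bp: int, right_bp: int) -> list[str]:
        """Markers on ``chrom`` with left_bp <= bp <= right_bp."""
        t = self.table
        sel = (t["chrom"] == chrom) & (t["bp"] >= left_bp) & (t["bp"] <= right_bp)
        return list(t.loc[sel, "marker"])

    def __eq__(self, other) -> bool:
        return isinstance(other, GeneticMap) and self.table.equals(other.table)


class GenotypeMatrix:
    """Homozygous biallelic calls for a strain panel, markers x strains.

    ``calls`` is a DataFrame indexed by marker id with one column per strain;
    cells hold ``"N2"``, ``"CB4856"`` or NaN (missing). A :class:`GeneticMap`
    may be attached; when present its marker order defines the row order.
    """

    def __init__(self, calls: pd.DataFrame, genetic_map: GeneticMap | None = None):
        bad = set(pd.unique(calls.values.ravel())) - set(ALLELES) - {np.nan, None}
        bad = {b for b in bad if not (isinstance(b, float) and np.isnan(b))}
        if bad:
            raise ValueError(f"calls contain non-allele values: {sorted(map(str, bad))}")
        if genetic_map is not None:
            extra = set(calls.index) - set(genetic_map.markers)
            if extra:
                raise ValueError(f"markers absent from map: {sorted(extra)[:5]}")
            calls = calls.reindex([m for m in genetic_map.markers if m in calls.index])
        self.calls = calls
        self.map = genetic_map

    @property
    def markers(self) -> pd.Index:
        return self.calls.index

    @property
    def strains(self) -> pd.Index:
        return self.calls.columns

    @property
    def n_strains(self) -> int:
        return self.calls.shape[1]

    def coded(self) -> pd.DataFrame:
        """Numeric +-1 coding (N2 -> -1, CB4856 -> +1), NaN for missing."""
        arr = self.calls.to_numpy(dtype=object)
        out = np.where(arr == "CB4856", 1.0, np.where(arr == "N2", -1.0, np.nan))
        return pd.DataFrame(out, index=self.calls.index, columns=self.calls.columns)

    def subset_strains(self, strains) -> "GenotypeMatrix":
        return GenotypeMatrix(self.calls[list(strains)], self.map)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, GenotypeMatrix)
            and self.calls.equals(other.calls)
            and (self.map == other.map if self.map is not None else other.map is None)
        )


@dataclass(frozen=True)
class QtlSpec:
    """A planted additive QTL for simulation: marker, effect in trait units.

    With +-1 allele coding the genetic contribution is ``additive_effect *
    code(allele)``, so the CB4856-vs-N2 class-mean difference equals
    ``2 * additive_effect``.
    """

    marker_id: str
    additive_effect: float
    trait_name: str = "trait"

    def __post_init__(self):
        if not np.isfinite(self.additive_effect):
            raise ValueError("additive_effect must be finite")


@dataclass(frozen=True)
class Threshold:
    """Genome-wide LOD significance threshold from a permutation null."""

    value: float
    n_permutations: int
    alpha: float
    seed: int | None = None

    def __post_init__(self):
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


@dataclass
class QtlRecord:
    """One detected QTL: the shape of a mapping-result table row."""

    trait: str
    chromosome: object
    interval_left_bp: int
    interval_right_bp: int
    peak_bp: int
    peak_marker: str
    lod: float
    variance_explained_pct: float = np.nan
    effect_size: float = np.nan
    iteration: int = 0

    def __post_init__(self):
        if not self.interval_left_bp <= self.peak_bp <= self.interval_right_bp:
            raise ValueError("peak_bp must lie inside the interval")


@dataclass
class RecapitulationCall:
    """Whether an introgression line reproduces a mapped QTL effect."""

    line: str
    background: str
    donor_allele: str
    recapitulated: bool
    p_vs_background: float
    direction_match: bool
    mean_diff: float = np.nan

    def __post_init__(self):
        if self.recapitulated and not self.direction_match:
            raise ValueError("recapitulated requires direction_match")
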