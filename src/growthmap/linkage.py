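"""Single-marker LOD linkage mapping with a cofactor forward search.

The statistic is the correlation LOD: for each marker,

    LOD = -n * ln(1 - R^2) / (2 ln 10)

with R the Pearson correlation between the +-1-coded genotypes and the trait
over the n strains with a genotype call at that marker. Genome-wide
significance comes from a permutation null: the trait is shuffled across
strains, the genome-wide maximum LOD recorded, and the threshold taken as the
ceil((1-alpha)*N)-th order statistic of N such maxima. QTL are mapped by a
forward search: the peak marker of each scan, if above threshold, is absorbed
as a cofactor (the trait is residualized on all cofactor genotypes by least
squares) and the scan repeats until no marker clears the threshold.
Confidence intervals are 1.5-LOD-drop regions around each peak.

Model objects
-------------
:class:`LinkageModel` holds an aligned (genotypes, trait) pair; ``fit()``
runs the forward search and returns :class:`LinkageResults` with the QTL
table (chromosome, interval, peak, LOD, variance explained, effect size),
per-iteration LOD profiles, and the threshold. Module-level functions
(:func:`lod_profile`, :func:`permutation_threshold`, :func:`forward_search`,
...) expose the same steps functionally.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core import GeneticMap, GenotypeMatrix, QtlRecord, Threshold

log = logging.getLogger(__name__)

_LN10_2 = 2.0 * np.log(10.0)
_R2_CLAMP = 1.0 - 1e-12


def lod_from_r2(r2, n):
    """LOD = -n * ln(1 - R^2) / (2 ln 10), with R^2 clamped below 1."""
    r2 = np.minimum(np.asarray(r2, dtype=float), _R2_CLAMP)
    return -np.asarray(n, dtype=float) * np.log1p(-r2) / _LN10_2


def lod_scores(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Per-marker correlation LOD for a strains x markers coded matrix.

    Missing genotypes are handled complete-case per marker, with that
    marker's own n in the formula. Monomorphic markers and zero-variance
    traits score 0.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = X.shape
    if y.shape != (n,):
        raise ValueError("trait length does not match genotype rows")
    if np.ptp(y) == 0:
        return np.zeros(m)
    nan_mask = np.isnan(X)
    if not nan_mask.any():
        return _lod_scores_dense(X, y[:, None]).ravel()
    out = np.empty(m)
    for j in range(m):
        ok = ~nan_mask[:, j]
        g, yy = X[ok, j], y[ok]
        if len(g) < 3 or np.ptp(g) == 0 or np.ptp(yy) == 0:
            out[j] = 0.0
            continue
        r = np.corrcoef(g, yy)[0, 1]
        out[j] = lod_from_r2(r * r, len(g))
    return out


def _lod_scores_dense(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """LOD for complete genotype matrix X (n x m) against traits Y (n x p).

    Returns an m x p array. One BLAS product computes all correlations.
    """
    n = X.shape[0]
    Xc = X - X.mean(axis=0)
    sx = Xc.std(axis=0)
    Yc = Y - Y.mean(axis=0)
    sy = Yc.std(axis=0)
    denom = np.outer(sx, sy) * n
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc.T @ Yc) / denom
    r[~np.isfinite(r)] = 0.0
    return lod_from_r2(r * r, n)


def _residualize_on(y: np.ndarray, C: np.ndarray | None) -> np.ndarray:
    """Least-squares residual of y on [intercept, C] (NaN in C mean-imputed)."""
    if C is None or C.shape[1] == 0:
        return y
    C = np.asarray(C, dtype=float).copy()
    if np.isnan(C).any():
        col_mean = np.nanmean(C, axis=0)
        idx = np.where(np.isnan(C))
        C[idx] = col_mean[idx[1]]
    D = np.column_stack([np.ones(len(y)), C])
    beta, *_ = np.linalg.lstsq(D, y, rcond=None)
    return y - D @ beta


@dataclass
class LodProfile:
    """Per-marker LOD scores for one trait and scan iteration."""

    table: pd.DataFrame  # marker, chrom, bp, lod
    trait_name: str = "trait"
    iteration: int = 0
    cofactors: tuple = ()

    def __post_init__(self):
        if (self.table["lod"] < 0).any():
            raise ValueError("LOD scores must be nonnegative")

    @property
    def lod(self) -> np.ndarray:
        return self.table["lod"].to_numpy()

    def peak(self) -> pd.Series:
        """Row of the maximum-LOD marker; ties go to the lowest coordinate."""
        return self.table.iloc[int(np.argmax(self.lod))]


def merge_pheno(
    genotypes: GenotypeMatrix, trait: pd.Series, min_shared: int = 10
) -> tuple[GenotypeMatrix, pd.Series]:
    """Align a genotype matrix and a trait vector on their shared strains."""
    shared = [s for s in genotypes.strains if s in trait.index]
    dropped = (len(genotypes.strains) - len(shared)) + (len(trait.index) - len(shared))
    if len(shared) < min_shared:
        raise ValueError(
            f"only {len(shared)} shared strains (need >= {min_shared})"
        )
    if dropped:
        log.info("merge_pheno dropped %d unmatched strain entries", dropped)
    return genotypes.subset_strains(shared), trait.loc[shared]


class LinkageModel:
    """Single-marker LOD mapping model for one trait on a RIAIL panel.

    Parameters
    ----------
    genotypes : GenotypeMatrix
        Marker x strain calls; a GeneticMap must be attached (or passed).
    trait : pd.Series
        Strain-indexed residual phenotype values.
    genetic_map : GeneticMap, optional
        Overrides the map attached to ``genotypes``.
    """

    def __init__(
        self,
        genotypes: GenotypeMatrix,
        trait: pd.Series,
        genetic_map: GeneticMap | None = None,
        min_shared: int = 10,
    ):
        gmap = genetic_map or genotypes.map
        if gmap is None:
            raise ValueError("a genetic map is required")
        if genetic_map is not None and genotypes.map is None:
            genotypes = GenotypeMatrix(genotypes.calls, genetic_map)
        self.genotypes, self.trait = merge_pheno(genotypes, trait, min_shared)
        self.map = gmap
        self.trait_name = trait.name or "trait"
        # strains x markers coded matrix, map order
        self._X = self.genotypes.coded().to_numpy().T
        self._y = self.trait.to_numpy(dtype=float)
        self._marker_table = self.map.table[self.map.table["marker"].isin(self.genotypes.markers)][
            ["marker", "chrom", "bp"]
        ].reset_index(drop=True)

    # -- scanning ---------------------------------------------------------

    def lod_profile(self, cofactors=(), iteration: int = 0) -> LodProfile:
        """Genome scan, residualizing the trait on cofactor genotypes first."""
        y = _residualize_on(self._y, self._cofactor_matrix(cofactors))
        lod = lod_scores(self._X, y)
        if np.all(lod == 0) and np.ptp(y) > 0:
            warnings.warn("all markers scored LOD 0 (monomorphic panel?)")
        table = self._marker_table.assign(lod=lod)
        return LodProfile(table, self.trait_name, iteration, tuple(cofactors))

    def _cofactor_matrix(self, cofactors):
        if not cofactors:
            return None
        idx = [self.genotypes.markers.get_loc(m) for m in cofactors]
        return self._X[:, idx]

    def permutation_threshold(
        self,
        n_permutations: int = 1000,
        alpha: float = 0.05,
        seed: int = 0,
        cofactors=(),
    ) -> Threshold:
        """Genome-wide threshold from the permutation null of the max LOD."""
        if n_permutations < 20:
            warnings.warn("fewer than 20 permutations: threshold quantile unstable")
        rng = np.random.default_rng(seed)
        y = _residualize_on(self._y, self._cofactor_matrix(cofactors))
        max_lod = _max_lod_null(self._X, y, n_permutations, rng)
        k = int(np.ceil((1.0 - alpha) * n_permutations))
        value = float(np.sort(max_lod)[k - 1])
        return Threshold(value, n_permutations, alpha, seed)

    # -- fitting ----------------------------------------------------------

    def fit(
        self,
        threshold: Threshold | float | None = None,
        n_permutations: int = 1000,
        alpha: float = 0.05,
        seed: int = 0,
        max_qtl: int = 10,
        drop: float = 1.5,
        recompute_threshold: bool = False,
    ) -> "LinkageResults":
        """Forward search: scan, absorb the peak as a cofactor, repeat.

        The threshold is computed once on the original trait and reused
        across iterations unless ``recompute_threshold`` is set.
        """
        if threshold is None:
            thr = self.permutation_threshold(n_permutations, alpha, seed)
        elif isinstance(threshold, Threshold):
            thr = threshold
        else:
            thr = Threshold(float(threshold), 1, alpha, None)
        cofactors: list[str] = []
        records: list[QtlRecord] = []
        profiles: list[LodProfile] = []
        for iteration in range(max_qtl + 1):
            profile = self.lod_profile(cofactors, iteration)
            profiles.append(profile)
            peak = profile.peak()
            if peak["lod"] <= thr.value or len(records) >= max_qtl:
                break
            y_scan = _residualize_on(self._y, self._cofactor_matrix(cofactors))
            left, right = lod_drop_interval(profile, peak["marker"], drop)
            var_pct, effect = annotate_peak(self.genotypes, y_scan, peak["marker"])
            records.append(
                QtlRecord(
                    trait=self.trait_name,
                    chromosome=peak["chrom"],
                    interval_left_bp=int(left),
                    interval_right_bp=int(right),
                    peak_bp=int(peak["bp"]),
                    peak_marker=peak["marker"],
                    lod=float(peak["lod"]),
                    variance_explained_pct=var_pct,
                    effect_size=effect,
                    iteration=iteration,
                )
            )
            cofactors.append(peak["marker"])
            if recompute_threshold:
                thr = replace(
                    self.permutation_threshold(
                        thr.n_permutations, thr.alpha, seed, cofactors
                    )
                )
        return LinkageResults(self, records, profiles, thr)


def _max_lod_null(X: np.ndarray, y: np.ndarray, n_perm: int, rng) -> np.ndarray:
    """Genome-wide max LOD for ``n_perm`` trait permutations."""
    n = len(y)
    if not np.isnan(X).any():
        perm = np.argsort(rng.random((n_perm, n)), axis=1)  # independent shuffles
        Y = y[perm].T  # n x n_perm
        return _lod_scores_dense(X, Y).max(axis=0)
    out = np.empty(n_perm)
    for b in range(n_perm):
        out[b] = lod_scores(X, rng.permutation(y)).max()
    return out


def lod_drop_interval(
    profile: LodProfile, peak_marker: str, drop: float = 1.5
) -> tuple[int, int]:
    """Confidence interval: contiguous same-chromosome run within ``drop``
    LOD of the peak, reported as [bp of first marker, bp of last marker]."""
    if drop < 0:
        raise ValueError("drop must be nonnegative")
    t = profile.table
    hit = t[t["marker"] == peak_marker]
    if hit.empty:
        raise KeyError(f"peak marker {peak_marker!r} not in profile")
    chrom = hit.iloc[0]["chrom"]
    sub = t[t["chrom"] == chrom].reset_index(drop=True)
    pos = int(sub.index[sub["marker"] == peak_marker][0])
    cutoff = sub.loc[pos, "lod"] - drop
    ok = (sub["lod"] >= cutoff).to_numpy()
    left = pos
    while left > 0 and ok[left - 1]:
        left -= 1
    right = pos
    while right < len(sub) - 1 and ok[right + 1]:
        right += 1
    return int(sub.loc[left, "bp"]), int(sub.loc[right, "bp"])


def annotate_peak(
    genotypes: GenotypeMatrix, trait, peak_marker: str
) -> tuple[float, float]:
    """(variance explained %, effect size) at a peak marker.

    Variance explained is 100 * R^2 between the coded genotype and the trait
    as scanned; effect size is mean(trait | CB4856) - mean(trait | N2).
    """
    g = genotypes.coded().loc[peak_marker].to_numpy()
    y = np.asarray(trait, dtype=float)
    ok = ~np.isnan(g)
    g, y = g[ok], y[ok]
    cb, n2 = y[g > 0], y[g < 0]
    if len(cb) == 0 or len(n2) == 0:
        raise ValueError(f"marker {peak_marker!r} has an empty allele class")
    if np.ptp(g) == 0 or np.ptp(y) == 0:
        return 0.0, float(cb.mean() - n2.mean())
    r = np.corrcoef(g, y)[0, 1]
    return float(100.0 * min(r * r, 1.0)), float(cb.mean() - n2.mean())


def annotate_qtl(
    record: QtlRecord, genotypes: GenotypeMatrix, trait
) -> QtlRecord:
    """Return a copy of ``record`` with variance explained and effect size
    computed from the trait as scanned in its detection iteration."""
    var_pct, effect = annotate_peak(genotypes, trait, record.peak_marker)
    out = replace(record)
    out.variance_explained_pct = var_pct
    out.effect_size = effect
    return out


QTL_COLUMNS = [
    "trait",
    "chromosome",
    "interval_left_bp",
    "interval_right_bp",
    "peak_bp",
    "peak_marker",
    "lod",
    "variance_explained_pct",
    "effect_size",
]


class LinkageResults:
    """Results of a forward-search linkage scan.

    Attributes
    ----------
    qtl : pd.DataFrame
        One row per detected QTL (possibly empty), columns ``QTL_COLUMNS``.
    profiles : list[LodProfile]
        The LOD profile of each scan iteration (last one found nothing).
    threshold : Threshold
        The genome-wide significance threshold applied.
    """

    def __init__(self, model, records, profiles, threshold):
        self.model = model
        self.records = records
        self.profiles = profiles
        self.threshold = threshold
        self.qtl = pd.DataFrame(
            [
                {c: getattr(r, "chromosome" if c == "chromosome" else c) for c in QTL_COLUMNS}
                for r in records
            ],
            columns=QTL_COLUMNS,
        )

    @property
    def n_qtl(self) -> int:
        return len(self.records)

    def summary(self) -> str:
        lines = [
            f"Linkage mapping: trait {self.model.trait_name!r}, "
            f"{self.model.genotypes.n_strains} strains, "
            f"{len(self.model.genotypes.markers)} markers",
            f"Threshold: LOD {self.threshold.value:.3f} "
            f"({self.threshold.n_permutations} permutations, "
            f"alpha={self.threshold.alpha})",
            f"QTL detected: {self.n_qtl}",
        ]
        if self.n_qtl:
            lines.append(
                self.qtl.to_string(
                    index=False,
                    float_format=lambda v: f"{v:.3f}",
                )
            )
        return "\n".join(lines)

    def plot(self, ax=None):
        """LOD profile of the first scan with the threshold and peaks."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(9, 3))
        t = self.profiles[0].table
        offset, ticks = 0.0, []
        for chrom, grp in t.groupby("chrom", sort=False):
            x = grp["bp"].to_numpy() / 1e6 + offset
            ax.plot(x, grp["lod"], lw=1)
            ticks.append((offset + x[-1]) / 2 if len(x) else offset)
            offset = x[-1]
        ax.axhline(self.threshold.value, ls="--", color="grey")
        ax.set_xticks(ticks, [str(c) for c in t["chrom"].drop_duplicates()])
        ax.set_ylabel("LOD")
        ax.set_xlabel("genomic position")
        return ax


# -- functional surface ----------------------------------------------------


def lod_profile(genotypes, trait, cofactors=()):
    """Genome scan for one trait; see :meth:`LinkageModel.lod_profile`."""
    return LinkageModel(genotypes, trait).lod_profile(cofactors)


def permutation_threshold(genotypes, trait, n_permutations=1000, alpha=0.05, seed=0):
    """Permutation threshold; see :meth:`LinkageModel.permutation_threshold`."""
    return LinkageModel(genotypes, trait).permutation_threshold(
        n_permutations, alpha, seed
    )


def forward_search(genotypes, trait, max_qtl=10, **fit_kwargs) -> "LinkageResults":
    """Run the full forward search; see :meth:`LinkageModel.fit`."""
    return LinkageModel(genotypes, trait).fit(max_qtl=max_qtl, **fit_kwargs)
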