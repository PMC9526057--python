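"""Two-dimensional genome scan for marker-pair interaction effects.

For each marker pair (a, b) the interaction LOD compares two nested linear
models of the trait on the +-1-coded genotypes:

    additive:  y ~ 1 + g_a + g_b
    full:      y ~ 1 + g_a + g_b + g_a * g_b

    LOD_int = (n / 2) * log10(RSS_additive / RSS_full)

Since the full model nests the additive one, RSS_full <= RSS_additive and the
interaction LOD is nonnegative. Genome-wide significance uses a permutation
null of the maximum interaction LOD over all scanned pairs, with the same
order-statistic threshold construction as the single-marker scan.

Pairs of (near-)collinear markers are excluded: identical genotype columns,
and same-chromosome pairs closer than a cM floor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import GenotypeMatrix, Threshold
from .linkage import merge_pheno

log = logging.getLogger(__name__)


def _pair_lods(Qa_add, Qa_full, Y, n):
    """Interaction LOD for one pair against every trait column of Y."""
    yty = np.einsum("ij,ij->j", Y, Y)
    rss_add = yty - np.einsum("ij,ij->j", Qa_add.T @ Y, Qa_add.T @ Y)
    rss_full = yty - np.einsum("ij,ij->j", Qa_full.T @ Y, Qa_full.T @ Y)
    rss_full = np.maximum(rss_full, 1e-300)
    ratio = np.maximum(rss_add / rss_full, 1.0)
    return (n / 2.0) * np.log10(ratio)


class InteractionScanModel:
    """Pairwise marker-interaction scan for one trait.

    Parameters mirror :class:`~growthmap.linkage.LinkageModel`; ``thin``
    keeps every thin-th marker to bound the pair count.
    """

    def __init__(self, genotypes: GenotypeMatrix, trait: pd.Series,
                 genetic_map=None, min_shared: int = 10):
        gmap = genetic_map or genotypes.map
        if gmap is None:
            raise ValueError("a genetic map is required")
        self.genotypes, self.trait = merge_pheno(genotypes, trait, min_shared)
        self.map = gmap
        self.trait_name = trait.name or "trait"

    def fit(
        self,
        thin: int = 1,
        n_permutations: int = 100,
        alpha: float = 0.05,
        seed: int = 0,
        min_cM: float = 1.0,
    ) -> "InteractionScanResults":
        """Scan all retained marker pairs and set a permutation threshold."""
        if thin < 1:
            raise ValueError("thin must be >= 1")
        mt = self.map.table[self.map.table["marker"].isin(self.genotypes.markers)]
        kept = mt.iloc[::thin].reset_index(drop=True)
        X = self.genotypes.coded().loc[kept["marker"]].to_numpy().T  # n x m
        if np.isnan(X).any():
            X = np.where(np.isnan(X), np.nanmean(X, axis=0, keepdims=True), X)
        y = self.trait.to_numpy(dtype=float)
        n, m = X.shape
        rng = np.random.default_rng(seed)
        perm = np.argsort(rng.random((n_permutations, n)), axis=1)
        Y = np.column_stack([y[:, None], y[perm].T])  # col 0 = observed trait
        chrom = kept["chrom"].to_numpy()
        cm = kept["cM"].to_numpy()
        ones = np.ones(n)
        rows = []
        max_per_column = np.zeros(Y.shape[1])
        for i in range(m - 1):
            gi = X[:, i]
            for j in range(i + 1, m):
                gj = X[:, j]
                if chrom[i] == chrom[j] and abs(cm[j] - cm[i]) < min_cM:
                    continue
                if np.array_equal(gi, gj) or np.array_equal(gi, -gj):
                    log.info("collinear pair skipped: %s/%s",
                             kept.loc[i, "marker"], kept.loc[j, "marker"])
                    continue
                D_add = np.column_stack([ones, gi, gj])
                D_full = np.column_stack([D_add, gi * gj])
                Qa, _ = np.linalg.qr(D_add)
                Qf, _ = np.linalg.qr(D_full)
                lods = _pair_lods(Qa, Qf, Y, n)
                max_per_column = np.maximum(max_per_column, lods)
                rows.append(
                    (kept.loc[i, "marker"], kept.loc[j, "marker"], float(lods[0]))
                )
        pairs = pd.DataFrame(rows, columns=["marker_a", "marker_b", "lod_interaction"])
        k = int(np.ceil((1.0 - alpha) * n_permutations))
        thr_value = float(np.sort(max_per_column[1:])[k - 1]) if n_permutations else np.inf
        threshold = Threshold(thr_value, n_permutations, alpha, seed)
        pairs["significant"] = pairs["lod_interaction"] > threshold.value
        return InteractionScanResults(self, pairs, threshold)


@dataclass
class InteractionScanResults:
    """Pair table with interaction LODs and the permutation threshold."""

    model: InteractionScanModel
    pairs: pd.DataFrame
    threshold: Threshold

    @property
    def significant(self) -> pd.DataFrame:
        return self.pairs[self.pairs["significant"]]

    def summary(self) -> str:
        lines = [
            f"Interaction scan: trait {self.model.trait_name!r}, "
            f"{len(self.pairs)} marker pairs",
            f"Threshold: interaction LOD {self.threshold.value:.3f} "
            f"({self.threshold.n_permutations} permutations, "
            f"alpha={self.threshold.alpha})",
            f"Significant pairs: {len(self.significant)}",
        ]
        if len(self.significant):
            lines.append(self.significant.to_string(index=False))
        return "\n".join(lines)


def scan_pairs(
    genotypes, trait, thin: int = 1, n_permutations: int = 100,
    alpha: float = 0.05, seed: int = 0, min_cM: float = 1.0,
) -> InteractionScanResults:
    """Functional wrapper around :class:`InteractionScanModel`."""
    return InteractionScanModel(genotypes, trait).fit(
        thin=thin, n_permutations=n_permutations, alpha=alpha, seed=seed,
        min_cM=min_cM,
    )
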