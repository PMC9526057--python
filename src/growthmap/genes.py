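"""Candidate-gene triage for a QTL confidence interval.

Given a gene annotation table, per-gene variant classes, and an eQTL table
(where each gene's expression maps), genes are partitioned the way a
candidate short-list for a mapped interval is usually built:

- in-interval genes with no variants and no eQTL mapping into the interval
  -> ``no_variation`` (eliminated);
- in-interval genes with any protein-coding variant OR an eQTL mapping into
  the interval -> ``protein_coding_or_eqtl`` (strong candidates);
- remaining in-interval genes (noncoding variants only)
  -> ``noncoding_only``;
- genes outside the interval whose eQTL maps into it -> ``outside_with_eqtl``.

The first three classes partition the in-interval genes; no gene is counted
twice. Genes overlapping hyper-divergent regions (where short-read variant
calls between wild strains are unreliable) are flagged, not reclassified.

Interval semantics: 1-based starts, half-open [start, end), any overlap.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

#: Variant classes that count as protein-coding variation.
CODING_CLASSES = frozenset(
    {"missense", "nonsense", "splice_site_coding", "frameshift", "inframe_indel"}
)


@dataclass(frozen=True)
class TriageTable:
    """Class counts for one interval's candidate-gene triage."""

    no_variation: int
    protein_coding_or_eqtl: int
    noncoding_only: int
    outside_with_eqtl: int

    @property
    def total(self) -> int:
        return (
            self.no_variation
            + self.protein_coding_or_eqtl
            + self.noncoding_only
            + self.outside_with_eqtl
        )

    @property
    def in_interval(self) -> int:
        return self.no_variation + self.protein_coding_or_eqtl + self.noncoding_only


def _overlaps(start_a, end_a, start_b, end_b) -> bool:
    """Half-open interval overlap."""
    return start_a < end_b and start_b < end_a


def classify_genes(
    interval: tuple,
    genes: pd.DataFrame,
    variants: pd.DataFrame | None = None,
    eqtl: pd.DataFrame | None = None,
    divergent: pd.DataFrame | None = None,
    coding_classes: frozenset = CODING_CLASSES,
) -> tuple[TriageTable, pd.DataFrame]:
    """Triage genes against a QTL interval.

    Parameters
    ----------
    interval : (chrom, left_bp, right_bp)
    genes : DataFrame with columns gene_id, chrom, start_bp, end_bp
    variants : DataFrame with columns gene_id, variant_class (one row per
        variant; classes outside ``coding_classes`` count as noncoding)
    eqtl : DataFrame with columns gene_id, target_chrom, target_bp — where
        each gene's expression association localizes
    divergent : DataFrame with columns chrom, start_bp, end_bp

    Returns the :class:`TriageTable` counts plus a per-gene label table with
    columns gene_id, in_interval, label, divergent_flag.
    """
    chrom, left, right = interval
    if genes["gene_id"].duplicated().any():
        dup = genes.loc[genes["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise ValueError(f"duplicate gene_id: {dup!r}")
    if (genes["start_bp"] >= genes["end_bp"]).any():
        raise ValueError("gene start_bp must be < end_bp")
    variants = variants if variants is not None else pd.DataFrame(columns=["gene_id", "variant_class"])
    eqtl = eqtl if eqtl is not None else pd.DataFrame(columns=["gene_id", "target_chrom", "target_bp"])

    var_classes = variants.groupby("gene_id")["variant_class"].apply(set)
    eqtl_in = (
        eqtl[(eqtl["target_chrom"] == chrom)
             & (eqtl["target_bp"] >= left) & (eqtl["target_bp"] < right)]
        .groupby("gene_id").size()
    )

    rows = []
    for g in genes.itertuples(index=False):
        inside = g.chrom == chrom and _overlaps(g.start_bp, g.end_bp, left, right)
        classes = var_classes.get(g.gene_id, set())
        has_eqtl_in = g.gene_id in eqtl_in.index
        if inside:
            if not classes and not has_eqtl_in:
                label = "no_variation"
            elif (classes & coding_classes) or has_eqtl_in:
                label = "protein_coding_or_eqtl"
            else:
                label = "noncoding_only"
        else:
            label = "outside_with_eqtl" if has_eqtl_in else "not_a_candidate"
        flag = False
        if divergent is not None and len(divergent):
            same = divergent[divergent["chrom"] == g.chrom]
            flag = any(
                _overlaps(g.start_bp, g.end_bp, d.start_bp, d.end_bp)
                for d in same.itertuples(index=False)
            )
        rows.append((g.gene_id, inside, label, flag))
    labels = pd.DataFrame(
        rows, columns=["gene_id", "in_interval", "label", "divergent_flag"]
    )
    counts = labels["label"].value_counts()
    table = TriageTable(
        no_variation=int(counts.get("no_variation", 0)),
        protein_coding_or_eqtl=int(counts.get("protein_coding_or_eqtl", 0)),
        noncoding_only=int(counts.get("noncoding_only", 0)),
        outside_with_eqtl=int(counts.get("outside_with_eqtl", 0)),
    )
    return table, labels
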