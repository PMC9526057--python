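"""Statistical validation of introgression lines (NILs and CSSs).

A validation assay measures a residual body-size trait for wells of each
strain: the two parents plus lines carrying a donor segment over a mapped
QTL. Analysis is a one-way ANOVA (phenotype ~ strain) with all-pairs
Tukey HSD, and a recapitulation call per line: the line recapitulates the
QTL iff it differs significantly from its background parent AND the sign of
the difference matches the direction predicted by the donor allele and the
QTL's effect size (CB4856 minus N2 orientation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .core import RecapitulationCall


def tukey_all_pairs(
    table: pd.DataFrame,
    value_col: str = "value",
    group_col: str = "strain",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """All-pairs Tukey HSD (Tukey-Kramer for unbalanced groups).

    Returns one row per unordered strain pair with the mean difference
    (group2 minus group1), the studentized-range adjusted p-value, and the
    familywise reject flag at ``alpha``.
    """
    counts = table.groupby(group_col)[value_col].count()
    if (counts < 2).any():
        small = counts[counts < 2].index.tolist()
        raise ValueError(f"groups with fewer than 2 observations: {small}")
    if np.isclose(table.groupby(group_col)[value_col].var(ddof=1).fillna(0), 0).all():
        raise ValueError("zero within-group variance in every group")
    res = pairwise_tukeyhsd(
        table[value_col].to_numpy(), table[group_col].to_numpy(), alpha=alpha
    )
    from itertools import combinations

    pairs = list(combinations(res.groupsunique, 2))
    return pd.DataFrame(
        {
            "strain_a": [a for a, _ in pairs],
            "strain_b": [b for _, b in pairs],
            "mean_diff": res.meandiffs.astype(float),
            "p_adj": res.pvalues.astype(float),
            "lower": res.confint[:, 0].astype(float),
            "upper": res.confint[:, 1].astype(float),
            "reject": res.reject,
        }
    )


def _pair_row(pairs: pd.DataFrame, a: str, b: str):
    """(mean(a) - mean(b), p_adj) for a pair regardless of stored order."""
    hit = pairs[(pairs["strain_a"] == b) & (pairs["strain_b"] == a)]
    if len(hit):
        return float(hit.iloc[0]["mean_diff"]), float(hit.iloc[0]["p_adj"])
    hit = pairs[(pairs["strain_a"] == a) & (pairs["strain_b"] == b)]
    if len(hit):
        return -float(hit.iloc[0]["mean_diff"]), float(hit.iloc[0]["p_adj"])
    raise KeyError(f"pair ({a}, {b}) missing from comparison table")


def call_recapitulation(
    pairs: pd.DataFrame,
    line: str,
    background: str,
    donor_allele: str,
    qtl_effect_size: float,
    alpha: float = 0.05,
) -> RecapitulationCall:
    """Decide whether an introgression line reproduces the mapped effect.

    ``qtl_effect_size`` follows the CB4856-minus-N2 convention, so a line
    carrying the CB4856 donor allele is predicted to shift the trait by
    sign(effect) relative to its background, and an N2 donor by the
    opposite sign.
    """
    if donor_allele not in ("N2", "CB4856"):
        raise ValueError("donor_allele must be 'N2' or 'CB4856'")
    diff, p = _pair_row(pairs, line, background)
    predicted = np.sign(qtl_effect_size) * (1 if donor_allele == "CB4856" else -1)
    direction_match = bool(predicted != 0 and np.sign(diff) == predicted)
    return RecapitulationCall(
        line=line,
        background=background,
        donor_allele=donor_allele,
        recapitulated=bool(p < alpha and direction_match),
        p_vs_background=p,
        direction_match=direction_match,
        mean_diff=diff,
    )


def validate_lines(
    assay: pd.DataFrame, design: list[dict], alpha: float = 0.05
) -> pd.DataFrame:
    """Tukey all-pairs plus a recapitulation call for each designed line.

    ``design`` entries need keys: line, background, donor_allele,
    qtl_effect_size. Returns one row per line.
    """
    pairs = tukey_all_pairs(assay, alpha=alpha)
    calls = [
        call_recapitulation(
            pairs, d["line"], d["background"], d["donor_allele"],
            d["qtl_effect_size"], alpha,
        )
        for d in design
    ]
    return pd.DataFrame(
        [
            {
                "line": c.line,
                "background": c.background,
                "donor_allele": c.donor_allele,
                "mean_diff": c.mean_diff,
                "p_vs_background": c.p_vs_background,
                "direction_match": c.direction_match,
                "recapitulated": c.recapitulated,
            }
            for c in calls
        ]
    )
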