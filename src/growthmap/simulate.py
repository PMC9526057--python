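"""Synthetic data with the statistical structure the pipeline assumes.

Generates genetic maps, recombinant inbred advanced intercross line (RIAIL)
panels, near-isogenic line (NIL) / chromosome substitution strain (CSS)
genotypes, phenotypes with planted additive QTL and batch effects, and raw
large-particle-sorter object clouds (an animal cluster plus debris clusters).

Recombination model
-------------------
RIAIL chromosomes are simulated directly as homozygous two-state Markov
chains: the first marker allele is Bernoulli(0.5) and the allele flips
between adjacent markers with probability

    r' = min(0.5, expansion * r_Haldane),   r_Haldane = (1 - exp(-2 d / 100)) / 2

where ``d`` is the adjacent-marker distance in cM. The ``expansion``
multiplier mimics the map expansion produced by extra intercross generations
in an advanced-intercross design. This reproduces the marginal allele
frequencies and the distance-decay of genotype correlation that single-marker
mapping relies on, at a fraction of the cost of pedigree simulation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import ALLELES, GeneticMap, GenotypeMatrix, QtlSpec

_CHROM_NAMES = ["I", "II", "III", "IV", "V", "X"]


def haldane_r(d_cM) -> np.ndarray:
    """Haldane map function: recombination fraction for a distance in cM."""
    d = np.asarray(d_cM, dtype=float)
    return (1.0 - np.exp(-2.0 * d / 100.0)) / 2.0


def _chrom_names(n: int) -> list[str]:
    if n <= len(_CHROM_NAMES):
        return _CHROM_NAMES[:n]
    return _CHROM_NAMES + [f"chr{i}" for i in range(len(_CHROM_NAMES) + 1, n + 1)]


def simulate_genetic_map(
    n_chromosomes: int = 6,
    markers_per_chromosome: int = 34,
    chrom_length_bp: int = 20_000_000,
    cM_per_Mb: float = 2.5,
    seed: int = 0,
    spacing: str = "even",
) -> GeneticMap:
    """Simulate a marker map with a linear bp-to-cM relationship.

    ``spacing="even"`` places markers at equal bp intervals spanning the
    chromosome; ``"random"`` draws marker positions uniformly at random.
    cM = bp * cM_per_Mb / 1e6 in both cases.
    """
    if n_chromosomes < 1 or markers_per_chromosome < 2:
        raise ValueError("need >=1 chromosome and >=2 markers per chromosome")
    if chrom_length_bp <= 0 or cM_per_Mb <= 0:
        raise ValueError("chrom_length_bp and cM_per_Mb must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    for chrom in _chrom_names(n_chromosomes):
        if spacing == "even":
            bp = np.linspace(1, chrom_length_bp, markers_per_chromosome)
        elif spacing == "random":
            bp = np.sort(rng.choice(chrom_length_bp, markers_per_chromosome, replace=False)) + 1
        else:
            raise ValueError(f"unknown spacing {spacing!r}")
        bp = bp.astype(np.int64)
        for i, pos in enumerate(bp):
            rows.append((f"{chrom}_{i + 1:03d}", chrom, int(pos), pos * cM_per_Mb / 1e6))
    return GeneticMap(pd.DataFrame(rows, columns=GeneticMap.COLUMNS))


def simulate_riail_genotypes(
    genetic_map: GeneticMap,
    n_strains: int,
    expansion: float = 3.0,
    seed: int = 0,
) -> GenotypeMatrix:
    """Simulate a fully homozygous RIAIL panel on the given map."""
    if n_strains < 2:
        raise ValueError("n_strains must be >= 2")
    if expansion < 1:
        raise ValueError("expansion must be >= 1")
    rng = np.random.default_rng(seed)
    blocks = []
    for chrom, grp in genetic_map.table.groupby("chrom", sort=False):
        d = np.diff(grp["cM"].to_numpy())
        r_prime = np.minimum(0.5, expansion * haldane_r(d))
        start = rng.random(n_strains) < 0.5
        flips = rng.random((len(d), n_strains)) < r_prime[:, None]
        # cumulative parity of flips determines the allele at each marker
        state = np.vstack([np.zeros(n_strains, bool), np.cumsum(flips, axis=0) % 2 == 1])
        blocks.append(np.where(state ^ start, ALLELES[1], ALLELES[0]))
    calls = pd.DataFrame(
        np.vstack(blocks),
        index=genetic_map.markers,
        columns=[f"RIAIL_{i + 1:04d}" for i in range(n_strains)],
    )
    return GenotypeMatrix(calls, genetic_map)


@dataclass
class TraitSimulation:
    """Simulated phenotype plus the planted truth for scoring."""

    values: pd.Series  # strain -> trait value
    truth: pd.DataFrame  # per-QTL: marker, additive_effect, variance_fraction
    batch: pd.Series | None = None  # strain -> batch label


def simulate_trait(
    genotypes: GenotypeMatrix,
    qtl: list[QtlSpec] | None = None,
    batch_labels=None,
    batch_sd: float = 0.0,
    noise_sd: float = 1.0,
    seed: int = 0,
    trait_name: str = "trait",
) -> TraitSimulation:
    """Simulate an additive trait: y = sum_k a_k * code(g_k) + batch + noise.

    Batch offsets are Normal(0, batch_sd^2), one draw per distinct batch
    label; residual noise is Normal(0, noise_sd^2) per strain. The truth
    record carries each QTL's expected variance fraction
    a_k^2 / (sum_j a_j^2 + batch_sd^2 + noise_sd^2).
    """
    if noise_sd <= 0:
        raise ValueError("noise_sd must be positive")
    qtl = qtl or []
    rng = np.random.default_rng(seed)
    coded = genotypes.coded()
    strains = genotypes.strains
    y = np.zeros(len(strains))
    for spec in qtl:
        if spec.marker_id not in coded.index:
            raise KeyError(f"QTL marker {spec.marker_id!r} not in genotypes")
        y = y + spec.additive_effect * coded.loc[spec.marker_id].to_numpy()
    batch = None
    if batch_labels is not None:
        batch = pd.Series(np.asarray(batch_labels), index=strains, name="batch")
        levels = batch.unique()
        offsets = dict(zip(levels, rng.normal(0.0, batch_sd, len(levels))))
        y = y + batch.map(offsets).to_numpy()
    y = y + rng.normal(0.0, noise_sd, len(strains))
    total_var = sum(s.additive_effect**2 for s in qtl) + batch_sd**2 + noise_sd**2
    truth = pd.DataFrame(
        {
            "marker": [s.marker_id for s in qtl],
            "additive_effect": [s.additive_effect for s in qtl],
            "variance_fraction": [s.additive_effect**2 / total_var for s in qtl],
        }
    )
    return TraitSimulation(pd.Series(y, index=strains, name=trait_name), truth, batch)


def effect_for_variance_fraction(fraction: float, noise_sd: float = 1.0) -> float:
    """Additive effect a with a^2/(a^2 + noise_sd^2) equal to ``fraction``.

    Under +-1 allele coding at allele frequency 0.5 the genetic variance of a
    single planted QTL is a^2.
    """
    if not 0 <= fraction < 1:
        raise ValueError("fraction must be in [0, 1)")
    return float(np.sqrt(fraction / (1.0 - fraction)) * noise_sd)


def simulate_nil_panel(
    genetic_map: GeneticMap,
    chrom,
    left_bp: int | None = None,
    right_bp: int | None = None,
) -> GenotypeMatrix:
    """Two parents plus reciprocal introgression lines over one interval.

    Returns four strains: ``N2``, ``CB4856``, ``NIL_CB4856_into_N2`` (donor
    CB4856 segment in an N2 background) and ``NIL_N2_into_CB4856``. Omitting
    the bp bounds introgresses the whole chromosome (a CSS).
    """
    t = genetic_map.table
    if chrom not in set(t["chrom"]):
        raise ValueError(f"chromosome {chrom!r} not in map")
    if left_bp is None:
        left_bp = int(t.loc[t["chrom"] == chrom, "bp"].min())
    if right_bp is None:
        right_bp = int(t.loc[t["chrom"] == chrom, "bp"].max())
    inside = genetic_map.markers_in(chrom, left_bp, right_bp)
    if not inside:
        raise ValueError("interval contains no markers")
    markers = genetic_map.markers
    n2 = pd.Series(ALLELES[0], index=markers)
    cb = pd.Series(ALLELES[1], index=markers)
    nil_cb = n2.copy()
    nil_cb[inside] = ALLELES[1]
    nil_n2 = cb.copy()
    nil_n2[inside] = ALLELES[0]
    calls = pd.DataFrame(
        {
            "N2": n2,
            "CB4856": cb,
            "NIL_CB4856_into_N2": nil_cb,
            "NIL_N2_into_CB4856": nil_n2,
        }
    )
    return GenotypeMatrix(calls, genetic_map)


def simulate_raw_sorter_objects(
    strains=("N2", "CB4856"),
    wells_per_strain: int = 6,
    hours=(48,),
    objects_per_well: int = 30,
    animal_log_tof=(5.7, 0.15),
    animal_log_ext=(4.6, 0.20),
    debris_log_tof=(3.4, 0.35),
    debris_log_ext=(2.3, 0.40),
    debris_fraction: float = 0.3,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate raw sorter object records: animals plus debris.

    Each object draws (TOF, EXT) from its component's log-normal; the ground
    truth component is kept in ``truth_label`` for scoring gating accuracy.
    Defaults emulate an L4-stage animal cloud with a smaller-object debris
    cloud (bacterial clumps, shed cuticles, next-generation larvae).
    """
    if not 0 <= debris_fraction <= 1:
        raise ValueError("debris_fraction must be in [0, 1]")
    for _, sd in (animal_log_tof, animal_log_ext, debris_log_tof, debris_log_ext):
        if sd <= 0:
            raise ValueError("log-scale sd must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    for strain in strains:
        for w in range(wells_per_strain):
            well = f"{strain}_w{w + 1:02d}"
            for hour in hours:
                is_debris = rng.random(objects_per_well) < debris_fraction
                mu_t = np.where(is_debris, debris_log_tof[0], animal_log_tof[0])
                sd_t = np.where(is_debris, debris_log_tof[1], animal_log_tof[1])
                mu_e = np.where(is_debris, debris_log_ext[0], animal_log_ext[0])
                sd_e = np.where(is_debris, debris_log_ext[1], animal_log_ext[1])
                tof = np.exp(rng.normal(mu_t, sd_t))
                ext = np.exp(rng.normal(mu_e, sd_e))
                for t, e, d in zip(tof, ext, is_debris):
                    rows.append((strain, well, hour, t, e, "debris" if d else "animal"))
    return pd.DataFrame(
        rows, columns=["strain", "well", "hour", "TOF", "EXT", "truth_label"]
    )


def simulate_assay_wells(
    genotypes: GenotypeMatrix,
    qtl: list[QtlSpec] | None = None,
    n_wells: int = 10,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-well phenotype replicates for a small strain panel (NIL assay).

    value = sum_k a_k * code(g_k at strain) + well noise. Returns a long
    table with columns strain, well, value, ready for all-pairs comparison.
    """
    if n_wells < 2:
        raise ValueError("need >=2 wells per strain")
    rng = np.random.default_rng(seed)
    qtl = qtl or []
    coded = genotypes.coded()
    rows = []
    for strain in genotypes.strains:
        g = sum(s.additive_effect * coded.at[s.marker_id, strain] for s in qtl)
        vals = g + rng.normal(0.0, noise_sd, n_wells)
        rows += [(strain, f"{strain}_w{i + 1:02d}", v) for i, v in enumerate(vals)]
    return pd.DataFrame(rows, columns=["strain", "well", "value"])
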