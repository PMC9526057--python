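"""Config-driven orchestration: simulate -> process -> map -> scan2 ->
validate -> triage, with a provenance manifest.

A run is described by a single YAML/dict config (see :func:`default_config`);
every stochastic stage has an explicit seed, and rerunning the same config
writes byte-identical tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, io, simulate, sorter
from .core import QtlSpec
from .genes import classify_genes
from .interactions import InteractionScanModel
from .linkage import LinkageModel
from .validation import validate_lines

log = logging.getLogger(__name__)

_REQUIRED_SECTIONS = ("seed", "simulate", "map", "scan2", "validate")


def default_config(seed: int = 17, outdir: str = "run") -> dict:
    """A complete demo configuration: one planted QTL on chromosome X."""
    return {
        "outdir": outdir,
        "seed": seed,
        "simulate": {
            "n_chromosomes": 6,
            "markers_per_chromosome": 34,
            "chrom_length_bp": 20_000_000,
            "cM_per_Mb": 2.5,
            "n_strains": 300,
            "expansion": 3.0,
            "qtl_variance_fraction": 0.086,
            "qtl_chromosome": "X",
            "noise_sd": 1.0,
            "n_batches": 3,
            "batch_sd": 0.5,
        },
        "process": {"debris_fraction": 0.3, "max_components": 3},
        "map": {"n_permutations": 1000, "alpha": 0.05, "drop": 1.5, "max_qtl": 10},
        "scan2": {"thin": 4, "n_permutations": 100, "alpha": 0.05},
        "validate": {"n_wells": 12, "noise_sd": 1.0},
    }


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def validate_config(config: dict) -> list[str]:
    """Return a list of schema problems (empty if the config is valid)."""
    problems = []
    for key in _REQUIRED_SECTIONS:
        if key not in config:
            problems.append(f"missing config section: {key}")
    sim = config.get("simulate", {})
    if sim.get("n_strains", 2) < 2:
        problems.append("simulate.n_strains must be >= 2")
    if not 0 < config.get("map", {}).get("alpha", 0.05) < 1:
        problems.append("map.alpha must be in (0, 1)")
    return problems


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: dict | str | Path, outdir: str | Path | None = None) -> Path:
    """Execute all stages; returns the run directory.

    Writes the genetic map, genotypes, trait, well summaries, QTL table,
    interaction-pair table, recapitulation calls, triage counts, a log, and
    a manifest with seeds, versions, and output hashes.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    problems = validate_config(config)
    if problems:
        raise ValueError("invalid config:\n" + "\n".join(problems))
    out = Path(outdir or config.get("outdir", "run"))
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config["seed"])
    timings = {}
    t0 = time.time()

    # -- simulate ---------------------------------------------------------
    sim = config["simulate"]
    gmap = simulate.simulate_genetic_map(
        sim["n_chromosomes"], sim["markers_per_chromosome"],
        sim["chrom_length_bp"], sim["cM_per_Mb"], seed=seed,
    )
    genotypes = simulate.simulate_riail_genotypes(
        gmap, sim["n_strains"], sim["expansion"], seed=seed + 1
    )
    chrom_markers = gmap.table[gmap.table["chrom"] == sim["qtl_chromosome"]]
    peak = chrom_markers.iloc[len(chrom_markers) // 2]["marker"]
    effect = simulate.effect_for_variance_fraction(
        sim["qtl_variance_fraction"], sim["noise_sd"]
    )
    spec = QtlSpec(peak, effect, "length")
    batches = [f"day{i % sim['n_batches'] + 1}" for i in range(sim["n_strains"])]
    trait_sim = simulate.simulate_trait(
        genotypes, [spec], batch_labels=batches, batch_sd=sim["batch_sd"],
        noise_sd=sim["noise_sd"], seed=seed + 2, trait_name="length",
    )
    io.write_genetic_map(gmap, out / "map.tsv")
    io.write_genotypes(genotypes, out / "genotypes.tsv")
    raw = simulate.simulate_raw_sorter_objects(
        debris_fraction=config["process"]["debris_fraction"], seed=seed + 3
    )
    io.write_table(raw, out / "raw_objects.tsv")
    timings["simulate"] = time.time() - t0

    # -- process ----------------------------------------------------------
    t1 = time.time()
    wells = sorter.process_sorter_table(
        raw.drop(columns=["truth_label"]),
        max_components=config["process"]["max_components"], seed=seed + 4,
    )
    io.write_table(wells, out / "wells.tsv")
    residual = sorter.residualize(trait_sim.values, trait_sim.batch)
    io.write_trait(residual, out / "trait_residual.tsv")
    timings["process"] = time.time() - t1

    # -- map --------------------------------------------------------------
    t2 = time.time()
    mp = config["map"]
    results = LinkageModel(genotypes, residual).fit(
        n_permutations=mp["n_permutations"], alpha=mp["alpha"],
        seed=seed + 5, max_qtl=mp["max_qtl"], drop=mp["drop"],
    )
    io.write_table(results.qtl, out / "qtl.tsv")
    (out / "mapping_summary.txt").write_text(results.summary() + "\n")
    timings["map"] = time.time() - t2

    # -- scan2 ------------------------------------------------------------
    t3 = time.time()
    sc = config["scan2"]
    scan = InteractionScanModel(genotypes, residual).fit(
        thin=sc["thin"], n_permutations=sc["n_permutations"],
        alpha=sc["alpha"], seed=seed + 6,
    )
    io.write_table(scan.pairs, out / "interaction_pairs.tsv")
    timings["scan2"] = time.time() - t3

    # -- validate ---------------------------------------------------------
    t4 = time.time()
    va = config["validate"]
    if len(results.qtl):
        q = results.qtl.iloc[0]
        nils = simulate.simulate_nil_panel(
            gmap, q["chromosome"], q["interval_left_bp"], q["interval_right_bp"]
        )
        assay = simulate.simulate_assay_wells(
            nils, [spec], n_wells=va["n_wells"], noise_sd=va["noise_sd"],
            seed=seed + 7,
        )
        design = [
            {"line": "NIL_CB4856_into_N2", "background": "N2",
             "donor_allele": "CB4856", "qtl_effect_size": q["effect_size"]},
            {"line": "NIL_N2_into_CB4856", "background": "CB4856",
             "donor_allele": "N2", "qtl_effect_size": q["effect_size"]},
        ]
        calls = validate_lines(assay, design)
    else:
        calls = pd.DataFrame()
    io.write_table(calls, out / "recapitulation_calls.tsv")
    timings["validate"] = time.time() - t4

    # -- triage (demo fixture around the mapped interval) -----------------
    t5 = time.time()
    if len(results.qtl):
        q = results.qtl.iloc[0]
        genes = _demo_gene_fixture(q["chromosome"], q["interval_left_bp"],
                                   q["interval_right_bp"])
        table, labels = classify_genes(
            (q["chromosome"], q["interval_left_bp"], q["interval_right_bp"]),
            *genes,
        )
        io.write_table(labels, out / "gene_labels.tsv")
        io.write_table(
            pd.DataFrame(
                [{"no_variation": table.no_variation,
                  "protein_coding_or_eqtl": table.protein_coding_or_eqtl,
                  "noncoding_only": table.noncoding_only,
                  "outside_with_eqtl": table.outside_with_eqtl,
                  "total": table.total}]
            ),
            out / "triage_counts.tsv",
        )
    timings["triage"] = time.time() - t5

    manifest = {
        "version": __version__,
        "seed": seed,
        "config": config,
        "timings_s": {k: round(v, 3) for k, v in timings.items()},
        "outputs": {
            p.name: _sha256(p) for p in sorted(out.glob("*.tsv"))
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return out


def _demo_gene_fixture(chrom, left, right):
    """Small synthetic gene/variant/eQTL tables spanning a mapped interval."""
    span = max(int(right) - int(left), 6)
    step = span // 6
    genes = pd.DataFrame(
        {
            "gene_id": [f"gene_{i}" for i in range(1, 7)],
            "chrom": [chrom] * 5 + [chrom],
            "start_bp": [int(left) + i * step for i in range(5)] + [int(right) + 10 * step],
            "end_bp": [int(left) + i * step + max(step // 2, 1) for i in range(5)]
            + [int(right) + 11 * step],
        }
    )
    variants = pd.DataFrame(
        {
            "gene_id": ["gene_2", "gene_3", "gene_4"],
            "variant_class": ["missense", "missense", "intronic"],
        }
    )
    eqtl = pd.DataFrame(
        {
            "gene_id": ["gene_5", "gene_6"],
            "target_chrom": [chrom, chrom],
            "target_bp": [int(left) + step, int(left) + 2 * step],
        }
    )
    return genes, variants, eqtl
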