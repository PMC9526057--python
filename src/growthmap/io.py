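"""Tab-separated readers/writers for the pipeline's tables.

All writers use a fixed column order and ``\\t`` separation so that reruns
with identical inputs are byte-stable.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .core import GeneticMap, GenotypeMatrix


def write_genetic_map(gmap: GeneticMap, path) -> None:
    gmap.table.to_csv(path, sep="\t", index=False)


def read_genetic_map(path) -> GeneticMap:
    return GeneticMap(pd.read_csv(path, sep="\t"))


def write_genotypes(genotypes: GenotypeMatrix, path) -> None:
    out = genotypes.calls.copy()
    out.insert(0, "marker", out.index)
    out.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_genotypes(path, genetic_map: GeneticMap | None = None) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    calls = df.set_index("marker")
    return GenotypeMatrix(calls, genetic_map)


def write_trait(trait: pd.Series, path) -> None:
    df = trait.rename_axis("strain").reset_index(name="value")
    df.insert(1, "trait", trait.name or "trait")
    df.to_csv(path, sep="\t", index=False)


def read_trait(path, trait_name: str | None = None) -> pd.Series:
    df = pd.read_csv(path, sep="\t")
    if trait_name is not None:
        df = df[df["trait"] == trait_name]
        if df.empty:
            raise ValueError(f"trait {trait_name!r} not found in {path}")
    name = df["trait"].iloc[0] if "trait" in df else trait_name or "trait"
    return pd.Series(df["value"].to_numpy(), index=pd.Index(df["strain"]), name=name)


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def ensure_exists(*paths) -> None:
    missing = [str(p) for p in paths if not Path(p).exists()]
    if missing:
        raise FileNotFoundError(f"missing input file(s): {missing}")
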