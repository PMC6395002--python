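"""TSV readers/writers for the pipeline's tabular schemas.

All tables are tab-separated with a header row.  Writers prepend provenance
comment lines (``# key: value``) recording the package version, the seed and
a hash of the generating configuration; readers skip ``#`` lines.  Column
names can be remapped through a *dialect* (a ``{file_column: canonical}``
mapping) so files from other pipelines do not hard-fail on header quirks.

Canonical schemas
-----------------
founder panel      : module, gene, initial_fitness[, se]
fitness table      : module, gene, population, replicate, value
mutation table     : population, founder_gene, founder_module, mutated_gene[, cluster]
revertant triplets : population, clone, fitness
interaction matrix : square, header row/column of gene names
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Mapping

import pandas as pd

from .mi import MutationTable

__all__ = [
    "SchemaError",
    "read_panel",
    "read_fitness_table",
    "read_mutation_table",
    "read_revertant_table",
    "read_interaction_matrix",
    "write_table",
    "write_interaction_matrix",
]

logger = logging.getLogger("compadapt")


class SchemaError(ValueError):
    """A required column is missing or rows reference unknown entities."""


def _read(path: str | Path, dialect: Mapping[str, str] | None) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    if dialect:
        df = df.rename(columns=dict(dialect))
    return df


def _require(df: pd.DataFrame, cols: list[str], path: str | Path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}; "
                          f"found {list(df.columns)}")


def read_panel(path: str | Path,
               dialect: Mapping[str, str] | None = None) -> pd.DataFrame:
    df = _read(path, dialect)
    _require(df, ["module", "gene", "initial_fitness"], path)
    if df["gene"].duplicated().any():
        dups = df.loc[df["gene"].duplicated(), "gene"].tolist()
        raise SchemaError(f"{path}: duplicate founder genes {dups}")
    if "se" not in df.columns:
        df["se"] = 0.0
    return df


def read_fitness_table(
    path: str | Path,
    panel: pd.DataFrame | None = None,
    dialect: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Read a replicate fitness table, validating against a panel if given.

    Rows with a missing fitness value are logged and dropped.  If the file
    has no ``module`` column the module is joined in from the panel.
    """
    df = _read(path, dialect)
    _require(df, ["gene", "population", "value"], path)
    n_missing = int(df["value"].isna().sum())
    if n_missing:
        logger.warning("%s: dropping %d rows with missing fitness",
                       path, n_missing)
        df = df[df["value"].notna()]
    if "replicate" not in df.columns:
        df["replicate"] = 1
    if panel is not None:
        unknown = sorted(set(df["gene"]) - set(panel["gene"]))
        if unknown:
            rows = df.index[df["gene"].isin(unknown)].tolist()[:10]
            raise SchemaError(
                f"{path}: unknown founder gene(s) {unknown} (rows {rows})"
            )
        if "module" not in df.columns:
            df = df.merge(panel[["gene", "module"]], on="gene", how="left")
    logger.info("%s: %d measurements across %d populations", path, len(df),
                df.groupby(["gene", "population"]).ngroups)
    return df.reset_index(drop=True)


def read_mutation_table(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
    uppercase_genes: bool = True,
    alias_map: Mapping[str, str] | None = None,
) -> MutationTable:
    """Read a long-format mutation table into a :class:`MutationTable`.

    Gene symbols are normalised to uppercase (systematic/standard names) and
    optionally remapped through ``alias_map``.  A row with an empty
    ``mutated_gene`` records a population with no called mutations.
    Duplicate (population, gene) rows are retained as a multiset; they only
    collapse at the indicator stage of the MI analysis.
    """
    df = _read(path, dialect)
    _require(df, ["population", "founder_gene", "founder_module",
                  "mutated_gene"], path)
    if uppercase_genes:
        df["mutated_gene"] = df["mutated_gene"].astype("string").str.upper()
    if alias_map:
        amap = {k.upper(): v for k, v in alias_map.items()}
        df["mutated_gene"] = df["mutated_gene"].map(
            lambda g: amap.get(g, g) if pd.notna(g) else g
        )
    logger.info("%s: %d rows, %d mutation records", path, len(df),
                int(df["mutated_gene"].notna().sum()))
    return MutationTable.from_frame(df)


def read_revertant_table(path: str | Path,
                         dialect: Mapping[str, str] | None = None) -> pd.DataFrame:
    df = _read(path, dialect)
    _require(df, ["population", "clone", "fitness"], path)
    return df


def read_interaction_matrix(path: str | Path) -> pd.DataFrame:
    """Square score matrix with a gene header row and index column.

    Long format (columns gene_a, gene_b, score) is also accepted and
    pivoted; missing pairs become NaN.
    """
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    if {"gene_a", "gene_b", "score"} <= set(df.reset_index().columns):
        long = df.reset_index()
        wide = long.pivot(index="gene_a", columns="gene_b", values="score")
        genes = sorted(set(wide.index) | set(wide.columns))
        return wide.reindex(index=genes, columns=genes)
    if list(df.index) != list(df.columns):
        raise SchemaError(f"{path}: row and column gene orders differ")
    return df


def _provenance(seed: int | None, config: object | None) -> list[str]:
    from . import __version__

    lines = [f"# compadapt: v{__version__}"]
    if seed is not None:
        lines.append(f"# seed: {seed}")
    if config is not None:
        digest = hashlib.sha256(
            json.dumps(str(config), sort_keys=True).encode()
        ).hexdigest()[:12]
        lines.append(f"# config_sha256: {digest}")
    return lines


def write_table(
    df: pd.DataFrame,
    path: str | Path,
    seed: int | None = None,
    config: object | None = None,
) -> None:
    """Write a TSV with provenance header comments."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for line in _provenance(seed, config):
            fh.write(line + "\n")
        df.to_csv(fh, sep="\t", index=False)


def write_interaction_matrix(
    matrix: pd.DataFrame, path: str | Path,
    seed: int | None = None, config: object | None = None,
) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for line in _provenance(seed, config):
            fh.write(line + "\n")
        matrix.to_csv(fh, sep="\t")
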