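"""Assemble and serialise the gene x organism percent-similarity matrix.

Each cell holds the chosen percent statistic (similarity by default,
identity optionally) of the global alignment between a reference gene and
its ortholog in one organism.  Cells with no ortholog are zero-filled — the
convention of the conservation heatmap, where absence in distant lineages
shows up as blocks of zeros — but a boolean presence mask is kept alongside
so that absence and genuine divergence remain distinguishable.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from orthoprofiler.alignment import GapPenalties, SubstitutionMatrix, needleman_wunsch

__all__ = ["SimilarityMatrix", "build_similarity_matrix", "write_matrix", "read_matrix"]


@dataclass
class SimilarityMatrix:
    """Genes (rows) x organisms (columns) percent statistics in [0, 100].

    ``values.loc[g, s]`` is 0 wherever ``presence.loc[g, s]`` is False.
    """

    values: pd.DataFrame
    presence: pd.DataFrame

    def __post_init__(self):
        if not self.values.index.equals(self.presence.index) or \
           not self.values.columns.equals(self.presence.columns):
            raise ValueError("values and presence must share index and columns")
        v = self.values.to_numpy(dtype=float)
        if np.any((v < 0) | (v > 100)):
            raise ValueError("similarity values must lie in [0, 100]")
        if np.any(v[~self.presence.to_numpy(dtype=bool)] != 0.0):
            raise ValueError("absent cells must be zero-filled")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def organism_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def build_similarity_matrix(
    human_proteome: Sequence[tuple[str, str]],
    species_proteomes: Mapping[str, Sequence[tuple[str, str]]],
    ortholog_table: Sequence[tuple[str, str, str]],
    matrix: SubstitutionMatrix | None = None,
    gaps: GapPenalties | None = None,
    stat_choice: Literal["similarity", "identity"] = "similarity",
    multi_ortholog: Literal["max", "mean"] = "max",
) -> SimilarityMatrix:
    """Align every reference gene against its ortholog(s) in every organism.

    ``ortholog_table`` rows are ``(human_gene, species, ortholog_id)``.
    When a (gene, species) pair maps to several orthologs the best hit
    (maximum statistic) is kept by default; ``multi_ortholog="mean"``
    averages instead.  Pairs missing from the table get 0 and a False
    presence flag.  Row order follows the reference proteome, column order
    the ``species_proteomes`` mapping.
    """
    if not ortholog_table:
        raise ValueError("ortholog table is empty")
    if stat_choice not in ("similarity", "identity"):
        raise ValueError(f"unknown stat_choice {stat_choice!r}")
    matrix = matrix if matrix is not None else SubstitutionMatrix.load("BLOSUM62")
    gaps = gaps if gaps is not None else GapPenalties()

    human = dict(human_proteome)
    seq_index: dict[str, dict[str, str]] = {
        sp: dict(records) for sp, records in species_proteomes.items()
    }
    genes = [g for g, _ in human_proteome]
    organisms = list(species_proteomes)

    per_cell: dict[tuple[str, str], list[float]] = {}
    for gene, species, oid in ortholog_table:
        if gene not in human:
            raise KeyError(f"ortholog table references unknown reference gene {gene!r}")
        if species not in seq_index:
            raise KeyError(f"ortholog table references unknown species {species!r}")
        if oid not in seq_index[species]:
            raise KeyError(f"ortholog id {oid!r} not found in proteome of {species!r}")
        res = needleman_wunsch(human[gene], seq_index[species][oid], matrix, gaps)
        stat = res.pct_similarity if stat_choice == "similarity" else res.pct_identity
        per_cell.setdefault((gene, species), []).append(stat)

    values = pd.DataFrame(0.0, index=genes, columns=organisms)
    presence = pd.DataFrame(False, index=genes, columns=organisms)
    for (gene, species), stats in per_cell.items():
        values.loc[gene, species] = max(stats) if multi_ortholog == "max" else float(np.mean(stats))
        presence.loc[gene, species] = True
    return SimilarityMatrix(values=values, presence=presence)


def write_matrix(sim: SimilarityMatrix, path: str | Path) -> None:
    """Write the matrix as TSV (2-decimal fixed point) and the presence
    mask alongside as ``<path>.mask.tsv``."""
    path = Path(path)
    sim.values.to_csv(path, sep="\t", float_format="%.2f", index_label="gene")
    sim.presence.astype(int).to_csv(path.with_suffix(path.suffix + ".mask.tsv"),
                                    sep="\t", index_label="gene")


def read_matrix(path: str | Path) -> SimilarityMatrix:
    """Read a matrix written by :func:`write_matrix`.

    If the mask sidecar is missing, presence defaults to ``value > 0``.
    """
    path = Path(path)
    try:
        values = pd.read_csv(path, sep="\t", index_col="gene")
    except ValueError as exc:
        raise ValueError(f"{path}: malformed similarity matrix: {exc}") from exc
    if values.isna().any().any():
        bad = values.index[values.isna().any(axis=1)][0]
        raise ValueError(f"{path}: non-numeric or missing cell in row {bad!r}")
    try:
        values = values.astype(float)
    except (TypeError, ValueError) as exc:
        bad = [r for r in values.index
               if not np.issubdtype(np.asarray(values.loc[r]).dtype, np.number)]
        raise ValueError(f"{path}: non-numeric cell in row {bad[0]!r}") from exc
    mask_path = path.with_suffix(path.suffix + ".mask.tsv")
    if mask_path.exists():
        presence = pd.read_csv(mask_path, sep="\t", index_col="gene").astype(bool)
    else:
        presence = values > 0
    return SimilarityMatrix(values=values, presence=presence)
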