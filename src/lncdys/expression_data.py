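"""Expression matrices, RPKM computation and gene biotype classing.

The central container is :class:`ExpressionMatrix`: a genes x samples grid
of RPKM values (optionally backed by raw read counts) together with a
sample -> group map ({"cancer", "normal"}). Annotation tables carry, per
gene, a biotype string and a transcript length in nucleotides; genes are
classed as protein-coding (PCG), long non-coding RNA (lncRNA: non-coding,
longer than 200 nt, not a housekeeping small-RNA biotype) or excluded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: biotypes never considered lncRNA regardless of length
DEFAULT_EXCLUDED_BIOTYPES = frozenset(
    {"rRNA", "tRNA", "miRNA", "snoRNA", "snRNA", "misc_RNA"}
)

#: strict lower bound on lncRNA transcript length, nucleotides
LNCRNA_MIN_LENGTH = 200

VALID_GROUPS = ("cancer", "normal")


class ExpressionDataError(ValueError):
    """Raised on malformed expression, annotation or group inputs."""


@dataclass
class ExpressionMatrix:
    """Genes x samples RPKM grid with group labels and optional counts.

    Parameters
    ----------
    values
        RPKM values, index = gene ids, columns = sample ids. Non-negative.
    group
        Maps every sample id to ``"cancer"`` or ``"normal"``.
    counts
        Optional raw read counts with the same shape/labels as ``values``.
    """

    values: pd.DataFrame
    group: pd.Series
    counts: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        v = self.values
        if v.index.duplicated().any():
            dupes = v.index[v.index.duplicated()].unique().tolist()
            raise ExpressionDataError(f"duplicated gene ids: {dupes[:5]}")
        if v.columns.duplicated().any():
            dupes = v.columns[v.columns.duplicated()].unique().tolist()
            raise ExpressionDataError(f"duplicated sample ids: {dupes[:5]}")
        if (v.to_numpy() < 0).any():
            raise ExpressionDataError("negative RPKM value in expression matrix")
        self.group = pd.Series(self.group)
        missing = [s for s in v.columns if s not in self.group.index]
        if missing:
            raise ExpressionDataError(
                f"samples missing from group table: {missing}"
            )
        bad = set(self.group.loc[list(v.columns)]) - set(VALID_GROUPS)
        if bad:
            raise ExpressionDataError(f"unknown group labels: {sorted(bad)}")
        self.group = self.group.loc[list(v.columns)]
        if self.counts is not None:
            if list(self.counts.index) != list(v.index) or list(
                self.counts.columns
            ) != list(v.columns):
                raise ExpressionDataError("counts do not align with RPKM grid")
            if (self.counts.to_numpy() < 0).any():
                raise ExpressionDataError("negative read count")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def samples_in(self, condition: str) -> list[str]:
        """Sample ids belonging to one condition ("cancer" or "normal")."""
        if condition not in VALID_GROUPS:
            raise ExpressionDataError(f"unknown condition {condition!r}")
        return [s for s in self.samples if self.group[s] == condition]

    def condition_values(self, condition: str) -> pd.DataFrame:
        """RPKM slice restricted to samples of one condition."""
        return self.values[self.samples_in(condition)]

    def condition_counts(self, condition: str) -> pd.DataFrame | None:
        if self.counts is None:
            return None
        return self.counts[self.samples_in(condition)]


def load_annotation(path: str | Path) -> pd.DataFrame:
    """Read a gene annotation TSV with columns gene_id, biotype, length."""
    ann = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "biotype": str})
    required = {"gene_id", "biotype", "length"}
    if not required.issubset(ann.columns):
        raise ExpressionDataError(
            f"annotation must have columns {sorted(required)}"
        )
    if ann["gene_id"].duplicated().any():
        raise ExpressionDataError("duplicated gene_id in annotation")
    if (ann["length"] < 1).any():
        raise ExpressionDataError("annotation length must be >= 1")
    return ann.set_index("gene_id")


def load_groups(path: str | Path) -> pd.Series:
    """Read a sample-group TSV with columns sample_id, group."""
    grp = pd.read_csv(path, sep="\t", dtype=str)
    if not {"sample_id", "group"}.issubset(grp.columns):
        raise ExpressionDataError("group table needs sample_id and group columns")
    if grp["sample_id"].duplicated().any():
        raise ExpressionDataError("duplicated sample_id in group table")
    return grp.set_index("sample_id")["group"]


def load_expression(
    path: str | Path,
    annotation_path: str | Path,
    group_path: str | Path,
) -> ExpressionMatrix:
    """Load an RPKM matrix TSV together with annotation and group tables.

    The matrix is tab-delimited with sample ids in the header row and gene
    ids in the first column. Genes absent from the annotation are dropped
    with a logged warning; a sample absent from the group table is an error.
    """
    mat = pd.read_csv(path, sep="\t", index_col=0)
    mat.index = mat.index.astype(str)
    ann = load_annotation(annotation_path)
    group = load_groups(group_path)

    unknown = [g for g in mat.index if g not in ann.index]
    if unknown:
        logger.warning(
            "dropping %d genes absent from annotation (e.g. %s)",
            len(unknown),
            unknown[:5],
        )
        mat = mat.drop(index=unknown)
    missing = [s for s in mat.columns if s not in group.index]
    if missing:
        raise ExpressionDataError(
            f"samples missing from group table: {missing}"
        )
    return ExpressionMatrix(values=mat, group=group)


def write_expression(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Write the RPKM grid as a TSV (genes in rows, samples in columns)."""
    matrix.values.to_csv(path, sep="\t")


def compute_rpkm(
    counts: pd.DataFrame,
    lengths: Mapping[str, float] | pd.Series,
    library_sizes: Mapping[str, float] | pd.Series,
) -> pd.DataFrame:
    """RPKM = count / (length/1e3) / (library_size/1e6).

    ``lengths`` maps gene -> transcript length in nucleotides and
    ``library_sizes`` maps sample -> total mapped reads. Zero counts map to
    zero RPKM; a zero or negative length or library size is an error.
    """
    lengths = pd.Series(lengths).loc[list(counts.index)].astype(float)
    lib = pd.Series(library_sizes).loc[list(counts.columns)].astype(float)
    if (lengths <= 0).any():
        raise ExpressionDataError("gene length must be positive")
    if (lib <= 0).any():
        raise ExpressionDataError("library size must be positive")
    kb = lengths.to_numpy()[:, None] / 1e3
    millions = lib.to_numpy()[None, :] / 1e6
    return pd.DataFrame(
        counts.to_numpy(dtype=float) / kb / millions,
        index=counts.index,
        columns=counts.columns,
    )


def classify_genes(
    annotation: pd.DataFrame,
    excluded_biotypes: Iterable[str] = DEFAULT_EXCLUDED_BIOTYPES,
) -> pd.Series:
    """Partition genes into PCG / lncRNA / excluded.

    ``protein_coding`` -> PCG. Any other biotype is non-coding; it is an
    lncRNA only when its transcript is strictly longer than 200 nt and the
    biotype is not one of the small/housekeeping RNA classes in
    ``excluded_biotypes``; everything else is excluded.
    """
    excluded = set(excluded_biotypes)
    biotype = annotation["biotype"]
    length = annotation["length"]
    cls = pd.Series("excluded", index=annotation.index, name="cls")
    cls[biotype == "protein_coding"] = "PCG"
    is_lnc = (
        (biotype != "protein_coding")
        & (length > LNCRNA_MIN_LENGTH)
        & ~biotype.isin(excluded)
    )
    cls[is_lnc] = "lncRNA"
    return cls
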