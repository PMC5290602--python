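"""Ingestion of per-study expression data.

A *study* is one two-group contrast (perturbed vs control) on a log2
expression matrix, together with its orientation metadata: whether the
perturbation removes the regulator's activity (``loss_of_function``, e.g. a
knockout) or adds it (``gain_of_function``, e.g. a transgene or a treatment
with the downstream cytokine). Matrices are assumed to be log2-normalized
upstream; this module never normalizes.

Probe-level matrices are collapsed to gene level with
:func:`collapse_probes`, the shared gene universe across studies is the
exact intersection (:func:`intersect_universe`), and fold-change signs are
put on a common orientation axis with :func:`harmonize_orientation` before
any cross-study integration.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import StudyRejectionError, ValidationError

ORIENTATIONS = ("loss_of_function", "gain_of_function")
GROUPS = ("perturbed", "control")
COLLAPSE_RULES = ("max_mean", "median")


@dataclass
class ExpressionStudy:
    """One study's log2 matrix plus its contrast and orientation metadata.

    Parameters
    ----------
    study_id
        Free-text identifier (e.g. a GEO accession).
    matrix
        Features (probes or genes) x samples, log2 intensity. All values
        must be finite and feature identifiers unique.
    sample_groups
        Series mapping each sample name to ``"perturbed"`` or ``"control"``.
        Both groups need at least 2 samples; smaller studies are rejected
        because no p-value can be computed from a single replicate.
    orientation
        ``"loss_of_function"`` or ``"gain_of_function"``.
    tissue
        Free-text tissue/cell-type label used by the Venn partitioning.
    feature_level
        ``"probe"`` or ``"gene"``.
    """

    study_id: str
    matrix: pd.DataFrame
    sample_groups: pd.Series
    orientation: str
    tissue: str = ""
    feature_level: str = "gene"

    def __post_init__(self) -> None:
        if self.orientation not in ORIENTATIONS:
            raise ValidationError(
                f"study {self.study_id!r}: orientation must be one of {ORIENTATIONS}, "
                f"got {self.orientation!r}"
            )
        if self.feature_level not in ("probe", "gene"):
            raise ValidationError(
                f"study {self.study_id!r}: feature_level must be 'probe' or 'gene'"
            )
        self.sample_groups = pd.Series(self.sample_groups)
        bad = set(self.sample_groups) - set(GROUPS)
        if bad:
            raise ValidationError(
                f"study {self.study_id!r}: unknown group labels {sorted(bad)}; "
                f"expected {GROUPS}"
            )
        missing = [s for s in self.matrix.columns if s not in self.sample_groups.index]
        if missing:
            raise ValidationError(
                f"study {self.study_id!r}: matrix columns {missing} are not listed "
                "in the sample sheet"
            )
        absent = [s for s in self.sample_groups.index if s not in self.matrix.columns]
        if absent:
            raise ValidationError(
                f"study {self.study_id!r}: sample(s) {absent} in the sample sheet "
                "are absent from the matrix"
            )
        for grp in GROUPS:
            n = int((self.sample_groups == grp).sum())
            if n < 2:
                raise StudyRejectionError(
                    f"study {self.study_id!r} rejected: group {grp!r} has {n} "
                    "sample(s); at least 2 per group are required"
                )
        if self.matrix.index.duplicated().any():
            dups = self.matrix.index[self.matrix.index.duplicated()].unique().tolist()
            raise ValidationError(
                f"study {self.study_id!r}: duplicate feature identifiers {dups[:5]}"
            )
        values = self.matrix.to_numpy(dtype=float)
        if not np.isfinite(values).all():
            raise ValidationError(
                f"study {self.study_id!r}: matrix contains non-finite intensities"
            )

    # -- convenience accessors -------------------------------------------------

    @property
    def perturbed_samples(self) -> list[str]:
        return [s for s in self.matrix.columns if self.sample_groups[s] == "perturbed"]

    @property
    def control_samples(self) -> list[str]:
        return [s for s in self.matrix.columns if self.sample_groups[s] == "control"]

    @property
    def n_perturbed(self) -> int:
        return len(self.perturbed_samples)

    @property
    def n_control(self) -> int:
        return len(self.control_samples)

    @property
    def genes(self) -> list[str]:
        return list(self.matrix.index)


@dataclass
class ProbeMap:
    """Many-to-one probe -> gene symbol map; probes without a gene are dropped."""

    entries: dict[str, str]

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "ProbeMap":
        entries: dict[str, str] = {}
        for probe, gene in pairs:
            if not gene or pd.isna(gene):
                continue
            if probe in entries and entries[probe] != gene:
                raise ValidationError(
                    f"probe {probe!r} maps to both {entries[probe]!r} and {gene!r}"
                )
            entries[probe] = str(gene)
        return cls(entries)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ProbeMap":
        """Read a 2-column TSV (probe_id, gene_symbol) with a header row."""
        df = pd.read_csv(path, sep="\t", dtype=str)
        if df.shape[1] < 2:
            raise ValidationError(f"probe map {path}: expected 2 columns")
        return cls.from_pairs(zip(df.iloc[:, 0], df.iloc[:, 1]))

    def __len__(self) -> int:
        return len(self.entries)


@dataclass(frozen=True)
class GeneUniverse:
    """Ordered (lexicographic) list of gene symbols common to a set of studies."""

    genes: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)

    def __contains__(self, gene) -> bool:
        return gene in set(self.genes)


def read_study(
    matrix_path: str | Path,
    samplesheet_path: str | Path,
    *,
    study_id: str,
    orientation: str,
    tissue: str = "",
    feature_level: str = "gene",
) -> ExpressionStudy:
    """Read an expression matrix TSV and its sample sheet into a validated study.

    The matrix TSV has the feature identifier in the first column and one
    column per sample; the sample sheet has columns ``sample_id`` and
    ``group`` (``perturbed``/``control``). Validation errors name the study
    and the offending sample.
    """
    matrix_path, samplesheet_path = Path(matrix_path), Path(samplesheet_path)
    for p in (matrix_path, samplesheet_path):
        if not p.exists():
            raise ValidationError(f"study {study_id!r}: file not found: {p}")
    matrix = pd.read_csv(matrix_path, sep="\t", index_col=0).astype(float)
    sheet = pd.read_csv(samplesheet_path, sep="\t", dtype=str)
    required = {"sample_id", "group"}
    if not required.issubset(sheet.columns):
        raise ValidationError(
            f"study {study_id!r}: sample sheet needs columns {sorted(required)}, "
            f"found {list(sheet.columns)}"
        )
    groups = pd.Series(sheet["group"].values, index=sheet["sample_id"].values)
    return ExpressionStudy(
        study_id=study_id,
        matrix=matrix,
        sample_groups=groups,
        orientation=orientation,
        tissue=tissue,
        feature_level=feature_level,
    )


def write_study(study: ExpressionStudy, outdir: str | Path) -> tuple[Path, Path]:
    """Write the matrix/sample-sheet TSV pair that :func:`read_study` consumes."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    matrix_path = outdir / f"{study.study_id}_matrix.tsv"
    sheet_path = outdir / f"{study.study_id}_samples.tsv"
    study.matrix.to_csv(matrix_path, sep="\t", index_label="feature", float_format="%.10g")
    sheet = pd.DataFrame(
        {"sample_id": study.sample_groups.index, "group": study.sample_groups.values}
    )
    sheet.to_csv(sheet_path, sep="\t", index=False)
    return matrix_path, sheet_path


def collapse_probes(
    study: ExpressionStudy, probe_map: ProbeMap, rule: str = "max_mean"
) -> ExpressionStudy:
    """Collapse a probe-level matrix to gene level.

    ``max_mean`` (default) keeps, for each gene, the single probe row with
    the highest mean intensity across all samples verbatim, so every
    gene-level value is traceable to an input probe. ``median`` takes the
    per-sample median over the gene's probes. Probes absent from the map are
    dropped. Ties under ``max_mean`` go to the lexicographically smallest
    probe id for determinism.
    """
    if study.feature_level != "probe":
        raise ValidationError(
            f"study {study.study_id!r}: collapse_probes requires a probe-level matrix"
        )
    if rule not in COLLAPSE_RULES:
        raise ValidationError(f"collapse rule must be one of {COLLAPSE_RULES}, got {rule!r}")
    mapped = [p for p in study.matrix.index if p in probe_map.entries]
    if not mapped:
        raise ValidationError(
            f"study {study.study_id!r}: no probe in the matrix is present in the probe map"
        )
    sub = study.matrix.loc[mapped]
    genes = pd.Series([probe_map.entries[p] for p in mapped], index=sub.index)
    if rule == "max_mean":
        means = sub.mean(axis=1)
        # stable winner per gene: highest mean, ties to smallest probe id
        order = pd.DataFrame({"gene": genes, "mean": means}).sort_values(
            ["gene", "mean"], ascending=[True, False], kind="mergesort"
        )
        winners = order[~order["gene"].duplicated()]
        collapsed = sub.loc[winners.index]
        collapsed.index = winners["gene"].values
        collapsed = collapsed.sort_index()
    else:  # median
        collapsed = sub.groupby(genes).median().sort_index()
    return dataclasses.replace(study, matrix=collapsed, feature_level="gene")


def harmonize_orientation(detable, convention: str):
    """Put a DE table's fold-change and effect signs on a common orientation axis.

    If the table's study orientation differs from ``convention``, all log2
    fold changes and signed statistics are negated; p-values, variances and
    degrees of freedom are untouched and the ``flipped`` flag records the
    sign flip. Applying the operation when orientations already agree is the
    identity, so flipping to the other convention and back restores the
    original table.
    """
    if convention not in ORIENTATIONS:
        raise ValidationError(f"convention must be one of {ORIENTATIONS}, got {convention!r}")
    if detable.orientation == convention:
        return detable
    table = detable.table.copy()
    for col in ("log2fc", "t_mod"):
        if col in table.columns:
            table[col] = -table[col]
    return dataclasses.replace(
        detable,
        table=table,
        orientation=convention,
        flipped=not detable.flipped,
    )


def intersect_universe(studies: Iterable[ExpressionStudy]) -> GeneUniverse:
    """Exact intersection of the studies' gene sets, lexicographically sorted."""
    studies = list(studies)
    if not studies:
        raise ValidationError("intersect_universe: no studies given")
    for s in studies:
        if s.feature_level != "gene":
            raise ValidationError(
                f"study {s.study_id!r} is at probe level; collapse probes first"
            )
    common: set[str] | None = None
    for s in studies:
        gene_set = set(s.matrix.index)
        common = gene_set if common is None else common & gene_set
    if not common:
        raise ValidationError("intersect_universe: the studies share no genes")
    return GeneUniverse(tuple(sorted(common)))
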