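"""Venn partitioning of significant gene sets across tissues.

Every gene in the union of the per-tissue significant sets is assigned
exactly one membership pattern (a bit string over the tissue order), a
``kT`` category (k = number of member tissues), and a direction label:
``up``/``down`` when the fold-change signs agree across all member tissues
and ``mixed`` when they disagree. Genes significant in all tissues with a
concordant direction are the tissue-independent core the analysis is
after.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .de import DETable
from .errors import ValidationError


@dataclass
class VennPartition:
    """Membership pattern, kT category and direction for each union gene."""

    tissues: tuple[str, ...]
    table: pd.DataFrame  # index gene; columns pattern, k, category, direction

    def pattern_counts(self) -> dict[str, int]:
        """Genes per membership pattern (e.g. '1011'), only non-empty patterns."""
        return self.table["pattern"].value_counts().sort_index().to_dict()

    def category_counts(self) -> dict[str, int]:
        """Genes per kT category ('1T', '2T', ...)."""
        return self.table["category"].value_counts().sort_index().to_dict()

    def members(self, tissue: str) -> list[str]:
        """All union genes significant in ``tissue``."""
        i = self.tissues.index(tissue)
        mask = self.table["pattern"].str[i] == "1"
        return sorted(self.table.index[mask])

    def __len__(self) -> int:
        return len(self.table)


def _as_sign_map(value) -> dict[str, int] | None:
    if isinstance(value, Mapping):
        return {g: int(np.sign(v)) for g, v in value.items()}
    return None


def venn_partition(sig_sets: Mapping[str, Iterable[str] | Mapping[str, float]]) -> VennPartition:
    """Partition the union of per-tissue significant sets by membership pattern.

    ``sig_sets`` maps tissue name (order-defining) to either a set of genes
    or a gene -> sign/log2FC mapping; when signs are supplied the direction
    labels are filled immediately, otherwise call
    :func:`direction_concordance` afterwards.
    """
    tissues = tuple(sig_sets)
    if not (2 <= len(tissues) <= 6):
        raise ValidationError(f"venn_partition supports 2-6 tissues, got {len(tissues)}")
    sign_maps: dict[str, dict[str, int] | None] = {}
    gene_sets: dict[str, set[str]] = {}
    for tissue, value in sig_sets.items():
        signs = _as_sign_map(value)
        sign_maps[tissue] = signs
        gene_sets[tissue] = set(signs) if signs is not None else set(value)
    union = sorted(set().union(*gene_sets.values()))
    if not union:
        raise ValidationError("venn_partition: the union of significant sets is empty")
    patterns = [
        "".join("1" if g in gene_sets[t] else "0" for t in tissues) for g in union
    ]
    k = [p.count("1") for p in patterns]
    table = pd.DataFrame(
        {
            "pattern": patterns,
            "k": k,
            "category": [f"{n}T" for n in k],
            "direction": pd.NA,
        },
        index=pd.Index(union, name="gene"),
    )
    part = VennPartition(tissues=tissues, table=table)
    if all(m is not None for m in sign_maps.values()):
        part = direction_concordance(part, sign_maps)  # type: ignore[arg-type]
    return part


def direction_concordance(
    partition: VennPartition,
    fc_tables: Mapping[str, Mapping[str, float] | DETable],
) -> VennPartition:
    """Label each union gene up/down/mixed from its member-tissue signs.

    ``fc_tables`` maps tissue to either a gene -> sign/log2FC mapping or a
    :class:`~demeta.de.DETable` (its ``log2fc`` column is used). A member
    tissue that cannot supply a sign for one of its genes is an error
    naming the gene and tissue.
    """
    sign_maps: dict[str, dict[str, int]] = {}
    for tissue in partition.tissues:
        if tissue not in fc_tables:
            raise ValidationError(f"direction_concordance: no fold changes for tissue {tissue!r}")
        src = fc_tables[tissue]
        if isinstance(src, DETable):
            sign_maps[tissue] = {
                g: int(np.sign(v)) for g, v in src.table["log2fc"].items()
            }
        else:
            sign_maps[tissue] = _as_sign_map(src) or {}
    directions = []
    for gene, row in partition.table.iterrows():
        signs = []
        for tissue, bit in zip(partition.tissues, row["pattern"]):
            if bit != "1":
                continue
            if gene not in sign_maps[tissue]:
                raise ValidationError(
                    f"direction_concordance: no sign for gene {gene!r} in tissue {tissue!r}"
                )
            signs.append(sign_maps[tissue][gene])
        if all(s > 0 for s in signs):
            directions.append("up")
        elif all(s < 0 for s in signs):
            directions.append("down")
        else:
            directions.append("mixed")
    table = partition.table.copy()
    table["direction"] = directions
    return VennPartition(tissues=partition.tissues, table=table)


def shared_core(partition: VennPartition, k: int | None = None) -> list[str]:
    """Genes significant in exactly ``k`` tissues (default: all of them)."""
    if k is None:
        k = len(partition.tissues)
    if k > len(partition.tissues):
        raise ValidationError(
            f"shared_core: k={k} exceeds the number of tissues ({len(partition.tissues)})"
        )
    return sorted(partition.table.index[partition.table["k"] == k])


def lookup_genes(
    genes: Iterable[str], tables: Iterable[DETable], alpha: float = 0.05
) -> pd.DataFrame:
    """Cross-examine a gene list against external DE tables.

    For each gene x table the entry is ``absent`` (gene not measured),
    ``not-significant`` (p >= alpha), or the regulator semantics under a
    loss-of-function reading: ``promoted`` (significant, down when the
    regulator is lost) or ``inhibited`` (significant, up). Gain-of-function
    tables are sign-flipped internally.
    """
    genes = list(genes)
    tables = list(tables)
    out = pd.DataFrame(
        index=pd.Index(genes, name="gene"),
        columns=[t.study_id for t in tables],
        dtype=object,
    )
    for det in tables:
        flip = -1.0 if det.orientation == "gain_of_function" else 1.0
        t = det.table
        for gene in genes:
            if gene not in t.index:
                out.loc[gene, det.study_id] = "absent"
                continue
            row = t.loc[gene]
            if row["p"] >= alpha:
                out.loc[gene, det.study_id] = "not-significant"
            else:
                eff = flip * row["log2fc"]
                out.loc[gene, det.study_id] = "promoted" if eff < 0 else "inhibited"
    return out


def write_partition(partition: VennPartition, path: str | Path) -> Path:
    """Partition TSV: gene, pattern, category, direction."""
    path = Path(path)
    partition.table.to_csv(path, sep="\t", index_label="gene")
    return path
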