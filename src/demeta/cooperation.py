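"""FC/FC quadrant cooperation analysis between two perturbation contrasts.

Two regulators whose perturbations are biochemically linked (e.g. a
protease knockout and a knockout of the substrate it degrades) predict a
definite *sign relation* between a gene's fold changes in the two
contrasts. ``expected_sign = -1`` encodes "cooperation predicts opposite
signs" (protease KO stabilizes the substrate, so substrate-responsive
genes move the other way), ``+1`` predicts the same sign.

Quadrant labels are semantic, not geometric: quadrant I is "reference
contrast up, comparator showing the cooperative sign", III its mirror with
the reference down, and II/IV the two non-cooperative sign combinations.
Genes significant in both contrasts with linear fold change at or above a
gate (default 2) on both axes are *gated*; the cooperative percentage is
taken over the gated genes, while the FC/FC R-squared is computed over all
paired genes.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .de import DETable
from .errors import ValidationError
from .io import GeneUniverse

logger = logging.getLogger(__name__)

QUADRANTS = ("I", "II", "III", "IV")


def pair_contrasts(
    table_x: DETable, table_y: DETable, universe: GeneUniverse | None = None
) -> pd.DataFrame:
    """Per-gene (fc_x, fc_y, p_x, p_y) over the genes shared by both tables.

    ``table_y`` is the reference contrast (plotted on the y-axis),
    ``table_x`` the comparator. Raw p-values are carried for gating.
    """
    shared = table_x.table.index.intersection(table_y.table.index)
    if universe is not None:
        shared = shared.intersection(pd.Index(list(universe)))
    if shared.empty:
        raise ValidationError(
            f"pair_contrasts: {table_x.study_id!r} and {table_y.study_id!r} share no genes"
        )
    shared = shared.sort_values()
    return pd.DataFrame(
        {
            "fc_x": table_x.table.loc[shared, "log2fc"],
            "fc_y": table_y.table.loc[shared, "log2fc"],
            "p_x": table_x.table.loc[shared, "p"],
            "p_y": table_y.table.loc[shared, "p"],
        },
        index=shared,
    )


@dataclass
class CooperationTable:
    """Paired fold changes with gate flags, quadrant labels and cooperation calls."""

    table: pd.DataFrame  # fc_x, fc_y, p_x, p_y, gated, quadrant, cooperative
    expected_sign: int
    gate: float
    alpha: float
    n_zero_excluded: int = 0

    @property
    def gated(self) -> pd.DataFrame:
        return self.table[self.table["gated"]]


def classify_quadrants(
    paired: pd.DataFrame,
    expected_sign: int,
    gate: float = 2.0,
    alpha: float = 0.05,
) -> CooperationTable:
    """Assign semantic quadrants and gate flags to paired fold changes.

    A gene is *gated* when it is significant in both contrasts
    (raw p < ``alpha``) and its linear fold change is no less than ``gate``
    on both axes. It is *cooperative* when sign(fc_x)*sign(fc_y) equals
    ``expected_sign`` (quadrants I and III). Genes with a fold change of
    exactly 0 on either axis carry no sign information and are excluded
    from quadrant labels (counted in ``n_zero_excluded``).
    """
    if expected_sign not in (-1, 1):
        raise ValidationError(f"expected_sign must be -1 or +1, got {expected_sign}")
    if gate < 1:
        raise ValidationError("gate is a linear fold change and must be >= 1")
    fc_x = paired["fc_x"].to_numpy(dtype=float)
    fc_y = paired["fc_y"].to_numpy(dtype=float)
    log_gate = math.log2(gate)
    nonzero = (fc_x != 0) & (fc_y != 0)
    n_zero = int((~nonzero).sum())
    if n_zero:
        logger.info("classify_quadrants: %d gene(s) with a zero fold change excluded", n_zero)
    coop = np.sign(fc_x) * np.sign(fc_y) == expected_sign
    quadrant = np.where(
        nonzero,
        np.where(
            coop,
            np.where(fc_y > 0, "I", "III"),
            np.where(fc_y > 0, "II", "IV"),
        ),
        "",
    )
    gated = (
        (paired["p_x"].to_numpy() < alpha)
        & (paired["p_y"].to_numpy() < alpha)
        & (np.abs(fc_x) >= log_gate)
        & (np.abs(fc_y) >= log_gate)
        & nonzero
    )
    table = paired.copy()
    table["gated"] = gated
    table["quadrant"] = quadrant
    table["cooperative"] = coop & nonzero
    return CooperationTable(
        table=table,
        expected_sign=expected_sign,
        gate=gate,
        alpha=alpha,
        n_zero_excluded=n_zero,
    )


def quadrant_counts(coop: CooperationTable) -> dict[str, int]:
    """Gated genes per semantic quadrant."""
    gated = coop.gated
    return {q: int((gated["quadrant"] == q).sum()) for q in QUADRANTS}


def cooperative_percentage(counts: Mapping[str, int]) -> float | None:
    """100 * (I + III) / total over the four quadrant counts, to 1 decimal.

    Returns None when no genes are gated (the percentage is undefined).
    """
    total = sum(counts.get(q, 0) for q in QUADRANTS)
    if total == 0:
        return None
    return round(100.0 * (counts.get("I", 0) + counts.get("III", 0)) / total, 1)


def cooperation_summary(coop: CooperationTable) -> dict:
    """Quadrant counts over gated genes, cooperative percentage and R-squared."""
    counts = quadrant_counts(coop)
    n_gated = sum(counts.values())
    return {
        "counts": counts,
        "n_gated": n_gated,
        "pct_cooperative": cooperative_percentage(counts),
        "r_squared": fc_fc_r_squared(coop.table),
        "n_zero_excluded": coop.n_zero_excluded,
        "expected_sign": coop.expected_sign,
        "gate": coop.gate,
        "alpha": coop.alpha,
    }


def fc_fc_r_squared(paired: pd.DataFrame, gated_only: bool = False) -> float:
    """Squared Pearson correlation of the paired log2 fold changes.

    Computed over all paired genes by default; ``gated_only`` restricts to
    gated genes when the table carries the flag. An axis with zero variance
    yields 0.0 with a warning.
    """
    t = paired
    if gated_only:
        if "gated" not in t.columns:
            raise ValidationError("fc_fc_r_squared: gated_only requires a classified table")
        t = t[t["gated"]]
    x = t["fc_x"].to_numpy(dtype=float)
    y = t["fc_y"].to_numpy(dtype=float)
    if x.size < 3:
        raise ValidationError("fc_fc_r_squared needs at least 3 paired genes")
    if np.var(x) == 0 or np.var(y) == 0:
        warnings.warn("fc_fc_r_squared: zero variance on an axis; returning 0.0")
        return 0.0
    r = float(np.corrcoef(x, y)[0, 1])
    return r * r


def write_cooperation(coop: CooperationTable, path: str | Path) -> Path:
    """CooperationTable TSV: gene, fc_x, fc_y, p_x, p_y, gated, quadrant, cooperative."""
    path = Path(path)
    coop.table.to_csv(path, sep="\t", index_label="gene", float_format="%.10g")
    return path
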