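"""Cross-study combination of differential-expression results.

Two complementary summaries are combined per gene across studies:

* a Hedges-type unbiased standardized mean difference derived from the
  moderated t-statistic,

      d  = t_mod * sqrt(1/n1 + 1/n2)
      J  = 1 - 3 / (4*m - 1),        m = df_total
      d' = J * d
      var(d') = (1/n1 + 1/n2) + d'^2 / (2*(n1 + n2))

  combined with fixed-effect inverse-variance weights (w = 1/var), giving
  z = d_comb / se_comb and a two-sided normal p, then BH-adjusted; and

* the log2 fold change itself, inverse-variance weighted using the per-gene
  standard error s_post * stdev_unscaled, with an optional
  DerSimonian-Laird random-effects model.

Fold-change signs must already be on a common orientation axis
(see :func:`demeta.io.harmonize_orientation`); :func:`meta_analyze` does
this for you.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .de import DETable, adjust_bh
from .errors import ValidationError
from .io import harmonize_orientation

logger = logging.getLogger(__name__)

COMBINE_METHODS = ("fixed", "random")


def effect_size(detable: DETable, n1: int | None = None, n2: int | None = None) -> pd.DataFrame:
    """Per-gene unbiased standardized effect sizes for one study.

    Returns a gene-indexed frame with columns ``study_id``, ``d`` (the
    bias-corrected standardized mean difference d'), ``var_d``, ``n1``,
    ``n2``. Requires a moderated table (``t_mod``/``df_total`` present) and
    ``df_total > 1``.
    """
    if not detable.moderated:
        raise ValidationError("effect_size: run empirical_bayes first (t_mod missing)")
    n1 = detable.n1 if n1 is None else n1
    n2 = detable.n2 if n2 is None else n2
    t = detable.table
    m = t["df_total"].to_numpy(dtype=float)
    if not (m > 1).all():
        raise ValidationError("effect_size: df_total must exceed 1")
    su = 1.0 / n1 + 1.0 / n2
    d_raw = t["t_mod"].to_numpy() * math.sqrt(su)
    J = np.where(np.isinf(m), 1.0, 1.0 - 3.0 / (4.0 * m - 1.0))
    d = J * d_raw
    var_d = su + d**2 / (2.0 * (n1 + n2))
    return pd.DataFrame(
        {"study_id": detable.study_id, "d": d, "var_d": var_d, "n1": n1, "n2": n2},
        index=t.index,
    )


def fold_change_records(detable: DETable) -> pd.DataFrame:
    """Per-gene (log2fc, se) rows for one study; se = sqrt(s2_post)*stdev_unscaled."""
    if not detable.moderated:
        raise ValidationError("fold_change_records: run empirical_bayes first")
    t = detable.table
    se = np.sqrt(t["s2_post"].to_numpy()) * t["stdev_unscaled"].to_numpy()
    return pd.DataFrame(
        {"study_id": detable.study_id, "log2fc": t["log2fc"].to_numpy(), "se": se},
        index=t.index,
    )


def combine_effect_sizes(records: pd.DataFrame) -> pd.DataFrame:
    """Fixed-effect inverse-variance combination of standardized effects.

    ``records`` is the row-wise concatenation of :func:`effect_size` frames
    (gene-indexed, columns ``d``, ``var_d``). Genes present in fewer
    studies are combined over the available studies, with ``k`` recorded.
    """
    if records.empty:
        raise ValidationError("combine_effect_sizes: no records")
    if not (records["var_d"].to_numpy() > 0).all():
        raise ValidationError("combine_effect_sizes: var_d must be positive")
    w = 1.0 / records["var_d"]
    g = pd.DataFrame({"w": w, "wd": w * records["d"]}).groupby(records.index)
    sums = g.sum()
    k = g.size()
    d_comb = sums["wd"] / sums["w"]
    se_comb = np.sqrt(1.0 / sums["w"])
    z = d_comb / se_comb
    p = 2.0 * stats.norm.sf(np.abs(z))
    out = pd.DataFrame(
        {"k": k, "d_comb": d_comb, "se_comb": se_comb, "z": z, "p": p},
    )
    out["p_adj"] = adjust_bh(out["p"].to_numpy())
    return out.sort_index()


def combine_fold_changes(records: pd.DataFrame, method: str = "fixed") -> pd.DataFrame:
    """Inverse-variance-weighted combined log2 fold change per gene.

    Fixed effect: w = 1/se^2, fc_comb = sum(w*fc)/sum(w),
    fc_se = sqrt(1/sum(w)), tau2 = 0. Random effects uses the
    DerSimonian-Laird tau^2 = max(0, (Q - (k-1)) / (sum(w) - sum(w^2)/sum(w)))
    and weights 1/(se^2 + tau2); for k = 1 the two coincide.
    """
    if method not in COMBINE_METHODS:
        raise ValidationError(f"method must be one of {COMBINE_METHODS}, got {method!r}")
    if records.empty:
        raise ValidationError("combine_fold_changes: no records")
    se = records["se"].to_numpy(dtype=float)
    if not (se > 0).all():
        raise ValidationError("combine_fold_changes: standard errors must be positive")
    fc = records["log2fc"]
    w = 1.0 / (records["se"] ** 2)
    g = pd.DataFrame({"w": w, "wf": w * fc, "w2": w**2, "wf2": w * fc**2}).groupby(records.index)
    sums = g.sum()
    k = g.size()
    fc_fixed = sums["wf"] / sums["w"]
    if method == "fixed":
        tau2 = pd.Series(0.0, index=sums.index)
        fc_comb = fc_fixed
        fc_se = np.sqrt(1.0 / sums["w"])
    else:
        # Q = sum w*(fc - fc_fixed)^2 expanded so it vectorizes per gene
        Q = sums["wf2"] - sums["wf"] ** 2 / sums["w"]
        C = sums["w"] - sums["w2"] / sums["w"]
        with np.errstate(invalid="ignore", divide="ignore"):
            tau2 = ((Q - (k - 1)) / C).clip(lower=0.0)
        tau2 = tau2.where((k > 1) & np.isfinite(tau2), 0.0)  # DL undefined for k=1
        wr = 1.0 / (records["se"] ** 2 + tau2.reindex(records.index).to_numpy())
        gr = pd.DataFrame({"w": wr, "wf": wr * fc}).groupby(records.index)
        rs = gr.sum()
        fc_comb = rs["wf"] / rs["w"]
        fc_se = np.sqrt(1.0 / rs["w"])
    out = pd.DataFrame(
        {"k_fc": k, "fc_comb": fc_comb, "fc_se": fc_se, "tau2": tau2}
    )
    return out.sort_index()


@dataclass
class MetaTable:
    """Combined per-gene results plus the per-study components behind them.

    ``table``: gene-indexed frame with ``k``, ``d_comb``, ``se_comb``,
    ``z``, ``p``, ``p_adj``, ``fc_comb``, ``fc_se``, ``tau2``,
    ``direction``. ``components``: long frame (one row per gene x study)
    with ``study_id``, ``d``, ``var_d``, ``log2fc``, ``se`` — the rows a
    forest plot displays.
    """

    table: pd.DataFrame
    components: pd.DataFrame
    convention: str = "loss_of_function"

    @property
    def genes(self) -> list[str]:
        return list(self.table.index)


def _direction(sign: np.ndarray, convention: str) -> np.ndarray:
    """Map harmonized effect signs to regulator semantics.

    Under the loss-of-function convention a negative combined fold change
    (gene goes down when the regulator is removed) means the regulator
    *promotes* the gene; positive means it *inhibits* it.
    """
    promoted_sign = -1 if convention == "loss_of_function" else 1
    out = np.where(sign == promoted_sign, "promoted", "inhibited")
    return np.where(sign == 0, "none", out)


def meta_analyze(
    detables: Iterable[DETable],
    method: str = "fixed",
    convention: str = "loss_of_function",
) -> MetaTable:
    """Harmonize orientations and combine effect sizes and fold changes.

    The result is invariant to the order of the input studies.
    """
    detables = [harmonize_orientation(d, convention) for d in detables]
    if not detables:
        raise ValidationError("meta_analyze: no studies")
    comp_frames = []
    for d in detables:
        es_d = effect_size(d)
        fc_d = fold_change_records(d)
        comp_frames.append(
            es_d.drop(columns=["n1", "n2"]).assign(
                log2fc=fc_d["log2fc"], se=fc_d["se"]
            )
        )
    es = pd.concat([effect_size(d) for d in detables])
    fcs = pd.concat([fold_change_records(d) for d in detables])
    table = combine_effect_sizes(es).join(
        combine_fold_changes(fcs, method=method), how="outer"
    )
    table["direction"] = _direction(np.sign(table["fc_comb"].to_numpy()), convention)
    components = pd.concat(comp_frames)
    components = components.sort_values("study_id", kind="mergesort").sort_index(kind="mergesort")
    return MetaTable(table=table, components=components, convention=convention)


def forest_rows(meta: MetaTable, gene: str) -> pd.DataFrame:
    """Per-study effect rows with 95% CIs followed by the combined row."""
    if gene not in meta.table.index:
        raise ValidationError(f"forest_rows: unknown gene {gene!r}")
    comp = meta.components.loc[[gene]]
    half = 1.96 * np.sqrt(comp["var_d"].to_numpy())
    rows = pd.DataFrame(
        {
            "label": comp["study_id"].to_numpy(),
            "estimate": comp["d"].to_numpy(),
            "ci_low": comp["d"].to_numpy() - half,
            "ci_high": comp["d"].to_numpy() + half,
        }
    )
    g = meta.table.loc[gene]
    comb_half = 1.96 * g["se_comb"]
    combined = pd.DataFrame(
        {
            "label": ["combined"],
            "estimate": [g["d_comb"]],
            "ci_low": [g["d_comb"] - comb_half],
            "ci_high": [g["d_comb"] + comb_half],
        }
    )
    return pd.concat([rows, combined], ignore_index=True)


def meta_significant(
    meta: MetaTable,
    alpha_adj: float = 0.05,
    fc_gate: float | None = None,
) -> pd.DataFrame:
    """Genes with adjusted p below ``alpha_adj`` (and, optionally, a linear FC gate).

    Returns a gene-indexed frame with ``direction`` (promoted/inhibited
    under the table's orientation convention), ``p_adj``, ``d_comb`` and
    ``fc_comb``, sorted by adjusted p.
    """
    t = meta.table
    mask = t["p_adj"].to_numpy() < alpha_adj
    if fc_gate is not None:
        if fc_gate < 1:
            raise ValidationError("fc_gate is a linear fold change and must be >= 1")
        mask &= np.abs(t["fc_comb"].to_numpy()) >= math.log2(fc_gate)
    out = t.loc[mask, ["direction", "p_adj", "d_comb", "fc_comb", "k"]]
    return out.sort_values("p_adj", kind="mergesort")


def write_metatable(meta: MetaTable, path: str | Path) -> Path:
    """Serialize the combined table as TSV (gene, k, d_comb, ..., direction)."""
    path = Path(path)
    meta.table.to_csv(path, sep="\t", index_label="gene", float_format="%.10g")
    return path
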