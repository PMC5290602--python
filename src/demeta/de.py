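"""Two-group differential expression with empirical-Bayes moderated t-statistics.

The model is the standard hierarchical one for gene-wise variances: the
residual variance of gene *g*, ``s2_g`` on ``df`` degrees of freedom, is
assumed to follow a scaled F-distribution around a prior variance ``s0_sq``
with ``d0`` prior degrees of freedom. The posterior (moderated) variance

    s2_post = (d0 * s0_sq + df * s2) / (d0 + df)

shrinks gene-wise variances toward the prior, and the moderated t

    t_mod = log2fc / (sqrt(s2_post) * stdev_unscaled)

follows a t-distribution on ``df + d0`` degrees of freedom under the null.
``(d0, s0_sq)`` are estimated by closed-form moment matching on
log-variances via digamma/trigamma functions. With small group sizes
(n ~ 3-5 per group) this moderation is what makes per-study p-values
usable at all.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError
from .io import ExpressionStudy

logger = logging.getLogger(__name__)

#: Columns present after fit_two_group (pre-moderation).
FIT_COLUMNS = ("log2fc", "s2", "df_resid", "stdev_unscaled")
#: Columns added by empirical_bayes.
EB_COLUMNS = ("s2_post", "t_mod", "df_total", "p", "p_adj")


@dataclass
class DETable:
    """Per-gene contrast estimates for one study.

    ``table`` is indexed by gene with columns ``log2fc`` (perturbed minus
    control), ``s2`` (pooled residual variance), ``df_resid``,
    ``stdev_unscaled`` (= sqrt(1/n1 + 1/n2)) and, after
    :func:`empirical_bayes`, ``s2_post``, ``t_mod``, ``df_total``, ``p``
    and ``p_adj`` (Benjamini-Hochberg). ``d0``/``s0_sq`` are the study-level
    variance-prior hyperparameters.
    """

    study_id: str
    table: pd.DataFrame
    n1: int
    n2: int
    orientation: str = "loss_of_function"
    tissue: str = ""
    d0: float | None = None
    s0_sq: float | None = None
    flipped: bool = False

    @property
    def moderated(self) -> bool:
        return "t_mod" in self.table.columns

    @property
    def genes(self) -> list[str]:
        return list(self.table.index)


def fit_two_group(study: ExpressionStudy) -> DETable:
    """Ordinary two-group fit: per-gene log2FC and pooled residual variance.

    log2fc = mean(perturbed) - mean(control); s2 is the pooled variance with
    df = n1 + n2 - 2; stdev_unscaled = sqrt(1/n1 + 1/n2). Moderated fields
    are added later by :func:`empirical_bayes`.
    """
    if study.feature_level != "gene":
        raise ValidationError(
            f"study {study.study_id!r}: fit_two_group requires a gene-level matrix"
        )
    pert = study.matrix[study.perturbed_samples].to_numpy(dtype=float)
    ctrl = study.matrix[study.control_samples].to_numpy(dtype=float)
    n1, n2 = pert.shape[1], ctrl.shape[1]
    log2fc = pert.mean(axis=1) - ctrl.mean(axis=1)
    ss = ((pert - pert.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
        (ctrl - ctrl.mean(axis=1, keepdims=True)) ** 2
    ).sum(axis=1)
    df_resid = n1 + n2 - 2
    s2 = ss / df_resid
    if not (s2 > 0).any():
        raise ValidationError(
            f"study {study.study_id!r}: zero residual variance for every gene; "
            "variance moderation is undefined"
        )
    table = pd.DataFrame(
        {
            "log2fc": log2fc,
            "s2": s2,
            "df_resid": float(df_resid),
            "stdev_unscaled": math.sqrt(1.0 / n1 + 1.0 / n2),
        },
        index=study.matrix.index,
    )
    return DETable(
        study_id=study.study_id,
        table=table,
        n1=n1,
        n2=n2,
        orientation=study.orientation,
        tissue=study.tissue,
    )


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration."""
    if x <= 0:
        raise ValidationError("trigamma inverse requires a positive argument")
    if x > 1e7:
        return 1.0 / math.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = float(special.polygamma(1, y))
        dif = tri * (1.0 - tri / x) / float(special.polygamma(2, y))
        y += dif
        if -dif / y < 1e-8:
            return y
    raise FloatingPointError("trigamma inverse did not converge")


def estimate_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-matching estimate of the variance prior (d0, s0_sq).

    Works on ``e = log(s2) - digamma(df/2) + log(df/2)`` whose theoretical
    mean and excess variance identify the prior: the excess of ``var(e)``
    over ``trigamma(df/2)`` equals ``trigamma(d0/2)``. When there is no
    excess (all s2 equal, or under-dispersed), ``d0 = +inf`` and ``s0_sq``
    is the pooled mean variance, which makes the posterior variance equal
    the common value exactly in the degenerate case.
    """
    s2 = np.asarray(s2, dtype=float)
    s2 = s2[s2 > 0]
    if s2.size < 2:
        raise ValidationError("estimate_prior needs at least 2 genes with positive variance")
    e = np.log(s2) - special.digamma(df / 2.0) + math.log(df / 2.0)
    evar = float(np.var(e, ddof=1)) - float(special.polygamma(1, df / 2.0))
    if evar > 0:
        try:
            d0 = 2.0 * _trigamma_inverse(evar)
            s0_sq = float(np.exp(np.mean(e) + special.digamma(d0 / 2.0) - math.log(d0 / 2.0)))
            return d0, s0_sq
        except FloatingPointError:
            logger.warning(
                "variance-prior moment matching failed to converge; "
                "falling back to d0=inf (common variance)"
            )
    return math.inf, float(np.mean(s2))


def empirical_bayes(
    detable: DETable, d0: float | None = None, s0_sq: float | None = None
) -> DETable:
    """Add moderated t, p and BH-adjusted p to a fitted table.

    ``d0``/``s0_sq`` override the moment-matching estimate when given
    (useful for forcing the ordinary-t limit ``d0=0`` or the pooled limit
    ``d0=inf``). Genes with ``s2 = 0`` get the prior-only posterior
    ``d0*s0_sq/(d0+df)``.
    """
    t = detable.table
    for col in FIT_COLUMNS:
        if col not in t.columns:
            raise ValidationError(f"empirical_bayes: fitted column {col!r} missing")
    df = float(t["df_resid"].iloc[0])
    if d0 is None or s0_sq is None:
        est_d0, est_s0 = estimate_prior(t["s2"].to_numpy(), df)
        d0 = est_d0 if d0 is None else d0
        s0_sq = est_s0 if s0_sq is None else s0_sq
    if not (d0 >= 0) or not (s0_sq > 0):
        raise ValidationError(f"invalid variance prior d0={d0}, s0_sq={s0_sq}")
    s2 = t["s2"].to_numpy(dtype=float)
    if math.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
        df_total = math.inf
    else:
        s2_post = (d0 * s0_sq + df * s2) / (d0 + df)
        df_total = df + d0
    with np.errstate(divide="ignore"):
        t_mod = t["log2fc"].to_numpy() / (np.sqrt(s2_post) * t["stdev_unscaled"].to_numpy())
    if math.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t_mod))
    else:
        p = 2.0 * stats.t.sf(np.abs(t_mod), df_total)
    out = t.copy()
    out["s2_post"] = s2_post
    out["t_mod"] = t_mod
    out["df_total"] = df_total
    out["p"] = p
    out["p_adj"] = adjust_bh(p)
    return replace(detable, table=out, d0=float(d0), s0_sq=float(s0_sq))


def adjust_bh(pvalues: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any():
        raise ValidationError("adjust_bh: NaN p-values in input")
    if (p < 0).any() or (p > 1).any():
        raise ValidationError("adjust_bh: p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass(frozen=True)
class SummaryFraction:
    """Count of significant genes out of the mapped total, with the percentage."""

    n_sig: int
    n_total: int

    def __post_init__(self) -> None:
        if not (0 <= self.n_sig <= self.n_total):
            raise ValidationError(
                f"SummaryFraction: need 0 <= n_sig <= n_total, got {self.n_sig}/{self.n_total}"
            )

    @property
    def pct(self) -> float:
        """100 * n_sig / n_total rounded to 1 decimal (0.0 for an empty universe)."""
        if self.n_total == 0:
            return 0.0
        return round(100.0 * self.n_sig / self.n_total, 1)


def significant_fraction(
    detable: DETable,
    alpha: float = 0.05,
    use_adjusted: bool = False,
    fc_gate: float | None = None,
) -> SummaryFraction:
    """Fraction of genes with p (or adjusted p) below ``alpha``.

    ``fc_gate`` is a *linear* fold-change threshold; when set, a gene must
    also satisfy ``|log2fc| >= log2(fc_gate)``.
    """
    t = detable.table
    col = "p_adj" if use_adjusted else "p"
    if col not in t.columns:
        raise ValidationError(f"significant_fraction: column {col!r} missing; run empirical_bayes")
    mask = t[col].to_numpy() < alpha
    if fc_gate is not None:
        if fc_gate < 1:
            raise ValidationError("fc_gate is a linear fold change and must be >= 1")
        mask &= np.abs(t["log2fc"].to_numpy()) >= math.log2(fc_gate)
    return SummaryFraction(n_sig=int(mask.sum()), n_total=int(len(t)))


# -- serialization -------------------------------------------------------------

_META_KEYS = ("study_id", "n1", "n2", "orientation", "tissue", "d0", "s0_sq", "flipped")


def write_detable(detable: DETable, path: str | Path) -> Path:
    """Write a DE table as TSV with study metadata in '#'-prefixed header lines."""
    path = Path(path)
    with open(path, "w") as fh:
        for key in _META_KEYS:
            fh.write(f"# {key}={getattr(detable, key)}\n")
        detable.table.to_csv(fh, sep="\t", index_label="gene", float_format="%.10g")
    return path


def read_detable(path: str | Path) -> DETable:
    """Read a DE table written by :func:`write_detable`."""
    path = Path(path)
    meta: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, value = line[1:].strip().partition("=")
            meta[key.strip()] = value
    table = pd.read_csv(path, sep="\t", comment="#", index_col="gene").astype(float)
    def _float(key):
        v = meta.get(key, "None")
        return None if v == "None" else float(v)
    return DETable(
        study_id=meta.get("study_id", path.stem),
        table=table,
        n1=int(meta["n1"]),
        n2=int(meta["n2"]),
        orientation=meta.get("orientation", "loss_of_function"),
        tissue=meta.get("tissue", ""),
        d0=_float("d0"),
        s0_sq=_float("s0_sq"),
        flipped=meta.get("flipped", "False") == "True",
    )
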