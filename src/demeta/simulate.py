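"""Synthetic multi-study expression data with planted truth tables.

The generator emulates the statistical structure of small-n knockout
microarray studies on disjoint tissues: per-gene variances drawn from a
scaled inverse-chi-squared prior (heavy-tailed, so empirical-Bayes
shrinkage matters), normal noise in log2 space, a small set of *global*
genes perturbed with a consistent sign in every study, larger
*tissue-specific* sets perturbed in one study each, and a paired
two-perturbation design with a specified sign relation for the cooperation
analysis. Effects are parameterized in units of the gene's own sigma
(standardized), so planted truth maps directly onto effect-size recovery.

One master seed spawns independent per-study substreams
(:class:`numpy.random.SeedSequence`), so study *i*'s matrix depends only on
the master seed and *i*, not on how many other studies are generated.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import ExpressionStudy

GLOBAL = "global"
SPECIFIC = "specific"
NULL = "null"
COOPERATIVE = "cooperative"
INDEPENDENT = "independent"
SINGLE = "single"


@dataclass
class SyntheticConfig:
    """Study conditions for the generator.

    Multi-study block: ``n_studies`` disjoint "tissues" with ``n1`` vs
    ``n2`` samples each, ``n_global`` genes perturbed by
    ``delta_global * sigma_g`` with one shared sign across studies, and
    ``n_specific`` genes per study perturbed by ``delta_specific * sigma_g``
    in that study only. Per-gene variances follow a scaled
    inverse-chi-squared prior with ``d0_true`` degrees of freedom and scale
    ``s0_sq_true``; baseline log2 intensities are N(baseline_mean,
    baseline_sd^2).

    Paired-perturbation block (:func:`generate_pair_perturbation`):
    ``n_regulated_pair`` genes perturbed in both contrasts at
    ``delta_pair * sigma_g``; a ``fraction_cooperative`` of them get sign
    product ``expected_sign`` across the two contrasts, the rest the
    opposite product; ``n_single`` additional genes respond in the
    reference contrast only.

    ``contaminate_fraction`` > 0 inflates the noise standard deviation of
    that fraction of samples by ``contaminate_inflation`` (a heavy-tailed
    misspecification knob for robustness checks; off by default).
    """

    n_genes: int = 5000
    n_studies: int = 4
    n1: int = 5
    n2: int = 5
    n_global: int = 40
    delta_global: float = 1.2
    n_specific: int = 150
    delta_specific: float = 1.5
    d0_true: float = 4.0
    s0_sq_true: float = 0.25
    baseline_mean: float = 8.0
    baseline_sd: float = 1.5
    n_regulated_pair: int = 250
    fraction_cooperative: float = 0.8
    expected_sign: int = -1
    delta_pair: float = 4.0
    n_single: int = 100
    contaminate_fraction: float = 0.0
    contaminate_inflation: float = 3.0

    def validate(self, paired: bool = False) -> None:
        if self.n_genes < 1 or self.n_studies < 1 or self.n1 < 2 or self.n2 < 2:
            raise ValidationError("SyntheticConfig: need n_genes/studies >= 1 and n1, n2 >= 2")
        if self.d0_true <= 0 or self.s0_sq_true <= 0:
            raise ValidationError("SyntheticConfig: variance prior must be positive")
        if self.expected_sign not in (-1, 1):
            raise ValidationError("SyntheticConfig: expected_sign must be -1 or +1")
        if not 0.0 <= self.fraction_cooperative <= 1.0:
            raise ValidationError("SyntheticConfig: fraction_cooperative must be in [0, 1]")
        if paired:
            planted = self.n_regulated_pair + self.n_single
        else:
            planted = self.n_global + self.n_studies * self.n_specific
        if planted > self.n_genes:
            raise ValidationError(
                f"SyntheticConfig: {planted} planted genes exceed n_genes={self.n_genes}"
            )


def _gene_names(n: int) -> pd.Index:
    return pd.Index([f"G{i:05d}" for i in range(n)], name="gene")


def _gene_level_params(config: SyntheticConfig, rng: np.random.Generator):
    """Baseline means and inverse-chi-squared per-gene variances."""
    mu = rng.normal(config.baseline_mean, config.baseline_sd, config.n_genes)
    sigma2 = config.d0_true * config.s0_sq_true / rng.chisquare(config.d0_true, config.n_genes)
    return mu, sigma2


def _study_matrix(
    study_id: str,
    mu: np.ndarray,
    sigma2: np.ndarray,
    effect: np.ndarray,
    config: SyntheticConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    n1, n2 = config.n1, config.n2
    sigma = np.sqrt(sigma2)
    noise = rng.normal(0.0, 1.0, (mu.size, n1 + n2)) * sigma[:, None]
    if config.contaminate_fraction > 0:
        mask = rng.random(n1 + n2) < config.contaminate_fraction
        noise[:, mask] *= config.contaminate_inflation
    data = mu[:, None] + noise
    data[:, :n1] += effect[:, None]
    cols = [f"{study_id}_p{i+1}" for i in range(n1)] + [
        f"{study_id}_c{i+1}" for i in range(n2)
    ]
    return pd.DataFrame(data, index=_gene_names(mu.size), columns=cols)


def _make_study(study_id, tissue, matrix, config) -> ExpressionStudy:
    groups = pd.Series(
        ["perturbed"] * config.n1 + ["control"] * config.n2, index=matrix.columns
    )
    return ExpressionStudy(
        study_id=study_id,
        matrix=matrix,
        sample_groups=groups,
        orientation="loss_of_function",
        tissue=tissue,
        feature_level="gene",
    )


def generate_multistudy(
    config: SyntheticConfig, seed: int
) -> tuple[list[ExpressionStudy], pd.DataFrame]:
    """Generate the multi-study design plus its truth table.

    The truth table is gene-indexed with a ``class`` column (``global``,
    ``specific``, ``null``), the owning study for specific genes, and one
    ``sign_<study>`` column per study (0 when the gene is unperturbed
    there). Deterministic given (config, seed).
    """
    config.validate(paired=False)
    children = np.random.SeedSequence(seed).spawn(config.n_studies + 1)
    shared = np.random.default_rng(children[0])
    mu, sigma2 = _gene_level_params(config, shared)
    names = _gene_names(config.n_genes)
    classes = np.full(config.n_genes, NULL, dtype=object)
    owner = np.full(config.n_genes, "", dtype=object)
    study_ids = [f"study{i+1}" for i in range(config.n_studies)]
    classes[: config.n_global] = GLOBAL
    global_sign = shared.choice([-1, 1], config.n_global)
    signs = {sid: np.zeros(config.n_genes, dtype=int) for sid in study_ids}
    start = config.n_global
    spec_slices = {}
    for sid in study_ids:
        sl = slice(start, start + config.n_specific)
        classes[sl] = SPECIFIC
        owner[sl] = sid
        spec_slices[sid] = sl
        start += config.n_specific
    studies = []
    for i, sid in enumerate(study_ids):
        rng = np.random.default_rng(children[i + 1])
        effect = np.zeros(config.n_genes)
        signs[sid][: config.n_global] = global_sign
        effect[: config.n_global] = (
            global_sign * config.delta_global * np.sqrt(sigma2[: config.n_global])
        )
        sl = spec_slices[sid]
        spec_sign = shared.choice([-1, 1], config.n_specific)
        signs[sid][sl] = spec_sign
        effect[sl] = spec_sign * config.delta_specific * np.sqrt(sigma2[sl])
        matrix = _study_matrix(sid, mu, sigma2, effect, config, rng)
        studies.append(_make_study(sid, f"tissue{i+1}", matrix, config))
    truth = pd.DataFrame({"class": classes, "study": owner}, index=names)
    for sid in study_ids:
        truth[f"sign_{sid}"] = signs[sid]
    return studies, truth


def generate_pair_perturbation(
    config: SyntheticConfig, seed: int
) -> tuple[ExpressionStudy, ExpressionStudy, pd.DataFrame]:
    """Generate the paired two-perturbation design for cooperation testing.

    Returns ``(study_x, study_y, truth)`` where ``study_y`` is the
    reference contrast and ``study_x`` the comparator. Cooperative genes
    have sign product ``expected_sign`` across the two contrasts,
    independent genes the opposite product, and ``single`` genes respond in
    the reference contrast only.
    """
    config.validate(paired=True)
    children = np.random.SeedSequence(seed).spawn(3)
    shared = np.random.default_rng(children[0])
    mu, sigma2 = _gene_level_params(config, shared)
    names = _gene_names(config.n_genes)
    n_coop = int(round(config.fraction_cooperative * config.n_regulated_pair))
    n_indep = config.n_regulated_pair - n_coop
    classes = np.full(config.n_genes, NULL, dtype=object)
    classes[:n_coop] = COOPERATIVE
    classes[n_coop : config.n_regulated_pair] = INDEPENDENT
    classes[config.n_regulated_pair : config.n_regulated_pair + config.n_single] = SINGLE
    sign_y = np.zeros(config.n_genes, dtype=int)
    sign_x = np.zeros(config.n_genes, dtype=int)
    n_planted = config.n_regulated_pair + config.n_single
    sign_y[:n_planted] = shared.choice([-1, 1], n_planted)
    sign_x[:n_coop] = config.expected_sign * sign_y[:n_coop]
    sign_x[n_coop : config.n_regulated_pair] = (
        -config.expected_sign * sign_y[n_coop : config.n_regulated_pair]
    )
    sigma = np.sqrt(sigma2)
    effect_y = sign_y * config.delta_pair * sigma
    effect_x = sign_x * config.delta_pair * sigma
    matrix_x = _study_matrix(
        "comparator", mu, sigma2, effect_x, config, np.random.default_rng(children[1])
    )
    matrix_y = _study_matrix(
        "reference", mu, sigma2, effect_y, config, np.random.default_rng(children[2])
    )
    study_x = _make_study("comparator", "comparator_tissue", matrix_x, config)
    study_y = _make_study("reference", "reference_tissue", matrix_y, config)
    truth = pd.DataFrame(
        {"class": classes, "sign_x": sign_x, "sign_y": sign_y}, index=names
    )
    return study_x, study_y, truth


def evaluate_recovery(
    called: Iterable[str], truth: pd.DataFrame, positive_class: str = GLOBAL
) -> dict:
    """Confusion metrics of a called gene list against the planted truth.

    ``sensitivity`` = called true positives / planted positives;
    ``fdr`` = false positives / called (0.0 for an empty call set).
    ``per_class`` counts how many called genes fall in each truth class.
    """
    called = set(called)
    unknown = called - set(truth.index)
    if unknown:
        raise ValidationError(f"evaluate_recovery: called genes not in truth: {sorted(unknown)[:5]}")
    positives = set(truth.index[truth["class"] == positive_class])
    tp = len(called & positives)
    fp = len(called - positives)
    per_class = truth.loc[sorted(called), "class"].value_counts().to_dict() if called else {}
    return {
        "n_called": len(called),
        "n_true": len(positives),
        "tp": tp,
        "fp": fp,
        "sensitivity": tp / len(positives) if positives else 0.0,
        "fdr": fp / len(called) if called else 0.0,
        "per_class": per_class,
    }
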