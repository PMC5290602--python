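import numpy as np
import pandas as pd
import pytest

from demeta.de import DETable
from demeta.io import ExpressionStudy


@pytest.fixture
def toy_study() -> ExpressionStudy:
    """4-sample (2 KO vs 2 WT) gene-level study with hand-checkable values."""
    matrix = pd.DataFrame(
        {
            "ko1": [5.0, 4.0, 7.0],
            "ko2": [5.0, 6.0, 7.5],
            "wt1": [3.0, 3.0, 7.2],
            "wt2": [3.0, 5.0, 7.1],
        },
        index=["gA", "gB", "gC"],
    )
    groups = pd.Series(
        {"ko1": "perturbed", "ko2": "perturbed", "wt1": "control", "wt2": "control"}
    )
    return ExpressionStudy(
        study_id="toy",
        matrix=matrix,
        sample_groups=groups,
        orientation="loss_of_function",
        tissue="aorta",
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


def make_detable(
    genes,
    log2fc,
    p=None,
    *,
    study_id="s",
    n1=5,
    n2=5,
    t_mod=None,
    df_total=10.0,
    s2_post=1.0,
    orientation="loss_of_function",
    tissue="",
) -> DETable:
    """Build a moderated DETable directly from arrays, for operator-level tests."""
    genes = list(genes)
    log2fc = np.asarray(log2fc, dtype=float)
    su = np.sqrt(1.0 / n1 + 1.0 / n2)
    s2_post = np.broadcast_to(np.asarray(s2_post, dtype=float), log2fc.shape).copy()
    if t_mod is None:
        t_mod = log2fc / (np.sqrt(s2_post) * su)
    t_mod = np.broadcast_to(np.asarray(t_mod, dtype=float), log2fc.shape).copy()
    if p is None:
        from scipy import stats

        p = 2.0 * stats.t.sf(np.abs(t_mod), df_total)
    p = np.broadcast_to(np.asarray(p, dtype=float), log2fc.shape).copy()
    from demeta.de import adjust_bh

    table = pd.DataFrame(
        {
            "log2fc": log2fc,
            "s2": s2_post,
            "df_resid": n1 + n2 - 2.0,
            "stdev_unscaled": su,
            "s2_post": s2_post,
            "t_mod": t_mod,
            "df_total": float(df_total),
            "p": p,
            "p_adj": adjust_bh(p),
        },
        index=pd.Index(genes, name="gene"),
    )
    return DETable(
        study_id=study_id,
        table=table,
        n1=n1,
        n2=n2,
        orientation=orientation,
        tissue=tissue,
        d0=float(df_total) - (n1 + n2 - 2.0),
        s0_sq=1.0,
    )
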