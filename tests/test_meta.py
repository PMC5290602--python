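import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from conftest import make_detable
from demeta.errors import ValidationError
from demeta.meta import (
    combine_effect_sizes,
    combine_fold_changes,
    effect_size,
    fold_change_records,
    forest_rows,
    meta_analyze,
    meta_significant,
)


class TestEffectSize:
    def test_null_gene(self):
        det = make_detable(["g"], [0.0], t_mod=[0.0], n1=4, n2=4)
        rec = effect_size(det)
        assert rec.loc["g", "d"] == 0.0
        assert rec.loc["g", "var_d"] == pytest.approx(1 / 4 + 1 / 4)

    def test_hand_evaluated_formulas(self):
        # n1=n2=5, t=2, m=10: d=2*sqrt(0.4)=1.264911, J=1-3/39=0.923077,
        # d'=1.167610, var=0.4+d'^2/20=0.468166
        det = make_detable(["g"], [1.0], t_mod=[2.0], n1=5, n2=5, df_total=10.0)
        rec = effect_size(det)
        assert rec.loc["g", "d"] == pytest.approx(
            2.0 * np.sqrt(0.4) * (1 - 3 / 39), abs=1e-12
        )
        assert rec.loc["g", "d"] == pytest.approx(1.16761, abs=1e-5)
        assert rec.loc["g", "var_d"] == pytest.approx(0.46817, abs=1e-4)

    def test_bias_correction_tends_to_one_with_df(self):
        ds = []
        for m in [4, 10, 50, 1000, np.inf]:
            det = make_detable(["g"], [1.0], t_mod=[2.0], n1=5, n2=5, df_total=m)
            ds.append(effect_size(det).loc["g", "d"])
        assert (np.diff(ds) > -1e-12).all()
        assert ds[-1] == pytest.approx(2.0 * np.sqrt(0.4))

    def test_nonpositive_df_rejected(self):
        det = make_detable(["g"], [1.0], t_mod=[2.0], df_total=1.0)
        with pytest.raises(ValidationError, match="df_total"):
            effect_size(det)


class TestCombineEffectSizes:
    def test_single_study_identity(self):
        rec = pd.DataFrame(
            {"study_id": "s1", "d": [0.8], "var_d": [0.5]}, index=["g"]
        )
        out = combine_effect_sizes(rec)
        assert out.loc["g", "d_comb"] == pytest.approx(0.8)
        assert out.loc["g", "z"] == pytest.approx(0.8 / np.sqrt(0.5))
        assert out.loc["g", "k"] == 1

    def test_two_equal_studies(self):
        rec = pd.DataFrame(
            {"study_id": ["s1", "s2"], "d": [0.8, 0.8], "var_d": [0.5, 0.5]},
            index=["g", "g"],
        )
        out = combine_effect_sizes(rec)
        assert out.loc["g", "d_comb"] == pytest.approx(0.8)
        assert out.loc["g", "se_comb"] == pytest.approx(0.5)  # sqrt(1/(2*2))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_random_records_match_formula_oracle(self, seed):
        r = np.random.default_rng(seed)
        d = r.normal(0, 1, 3)
        v = r.uniform(0.1, 2.0, 3)
        rec = pd.DataFrame(
            {"study_id": ["a", "b", "c"], "d": d, "var_d": v}, index=["g"] * 3
        )
        out = combine_effect_sizes(rec)
        w = 1 / v
        assert out.loc["g", "d_comb"] == pytest.approx((w * d).sum() / w.sum())
        assert out.loc["g", "se_comb"] == pytest.approx(np.sqrt(1 / w.sum()))
        z = out.loc["g", "z"]
        assert out.loc["g", "p"] == pytest.approx(2 * stats.norm.sf(abs(z)))

    def test_combined_variance_never_exceeds_smallest_study_variance(self, rng):
        for _ in range(20):
            k = rng.integers(1, 6)
            v = rng.uniform(0.05, 2.0, k)
            rec = pd.DataFrame(
                {"study_id": [f"s{i}" for i in range(k)], "d": rng.normal(0, 1, k),
                 "var_d": v},
                index=["g"] * k,
            )
            out = combine_effect_sizes(rec)
            assert out.loc["g", "se_comb"] ** 2 <= v.min() + 1e-12


class TestCombineFoldChanges:
    def test_equal_weight_mean(self):
        rec = pd.DataFrame(
            {"study_id": ["a", "b"], "log2fc": [1.0, 2.0], "se": [1.0, 1.0]},
            index=["g", "g"],
        )
        out = combine_fold_changes(rec)
        assert out.loc["g", "fc_comb"] == pytest.approx(1.5)
        assert out.loc["g", "fc_se"] == pytest.approx(np.sqrt(0.5))

    def test_single_study_identity(self):
        rec = pd.DataFrame(
            {"study_id": ["a"], "log2fc": [1.3], "se": [0.7]}, index=["g"]
        )
        for method in ("fixed", "random"):
            out = combine_fold_changes(rec, method=method)
            assert out.loc["g", "fc_comb"] == pytest.approx(1.3)
            assert out.loc["g", "fc_se"] == pytest.approx(0.7)
            assert out.loc["g", "tau2"] == 0.0

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_fixed_matches_weighted_mean_oracle(self, seed):
        r = np.random.default_rng(seed)
        fc = r.normal(0, 2, 5)
        se = r.uniform(0.2, 1.5, 5)
        rec = pd.DataFrame(
            {"study_id": list("abcde"), "log2fc": fc, "se": se}, index=["g"] * 5
        )
        out = combine_fold_changes(rec)
        w = 1 / se**2
        assert out.loc["g", "fc_comb"] == pytest.approx((w * fc).sum() / w.sum())
        assert out.loc["g", "fc_se"] == pytest.approx(np.sqrt(1 / w.sum()))

    def test_random_effects_tau2_zero_when_fold_changes_identical(self):
        rec = pd.DataFrame(
            {"study_id": list("abc"), "log2fc": [0.9] * 3, "se": [0.3, 0.5, 0.7]},
            index=["g"] * 3,
        )
        out = combine_fold_changes(rec, method="random")
        assert out.loc["g", "tau2"] == 0.0
        assert out.loc["g", "fc_comb"] == pytest.approx(0.9)

    def test_dersimonian_laird_hand_oracle(self):
        fc = np.array([0.2, 1.4, -0.5])
        se = np.array([0.4, 0.6, 0.5])
        rec = pd.DataFrame(
            {"study_id": list("abc"), "log2fc": fc, "se": se}, index=["g"] * 3
        )
        w = 1 / se**2
        fixed = (w * fc).sum() / w.sum()
        Q = (w * (fc - fixed) ** 2).sum()
        C = w.sum() - (w**2).sum() / w.sum()
        tau2 = max(0.0, (Q - 2) / C)
        wr = 1 / (se**2 + tau2)
        out = combine_fold_changes(rec, method="random")
        assert out.loc["g", "tau2"] == pytest.approx(tau2)
        assert out.loc["g", "fc_comb"] == pytest.approx((wr * fc).sum() / wr.sum())
        assert out.loc["g", "fc_se"] == pytest.approx(np.sqrt(1 / wr.sum()))


def _three_studies(rng, n_genes=40):
    dets = []
    for i, sid in enumerate("abc"):
        fc = rng.normal(0, 1, n_genes)
        dets.append(
            make_detable(
                [f"g{j:02d}" for j in range(n_genes)], fc,
                study_id=sid, s2_post=rng.uniform(0.2, 1.0, n_genes),
            )
        )
    return dets


class TestMetaAnalyze:
    def test_study_order_invariance(self, rng):
        dets = _three_studies(rng)
        a = meta_analyze(dets)
        b = meta_analyze(dets[::-1])
        pd.testing.assert_frame_equal(a.table, b.table)
        pd.testing.assert_frame_equal(a.components, b.components)

    def test_mixed_orientations_are_harmonized(self, rng):
        import dataclasses

        dets = _three_studies(rng)
        flipped = dataclasses.replace(
            dets[0],
            orientation="gain_of_function",
            table=dets[0].table.assign(
                log2fc=-dets[0].table["log2fc"], t_mod=-dets[0].table["t_mod"]
            ),
        )
        a = meta_analyze(dets)
        b = meta_analyze([flipped, dets[1], dets[2]])
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_genes_missing_from_some_studies_keep_partial_k(self, rng):
        dets = _three_studies(rng, n_genes=10)
        dets[2] = make_detable(["g00", "g01"], [1.0, -1.0], study_id="c")
        out = meta_analyze(dets)
        assert out.table.loc["g00", "k"] == 3
        assert out.table.loc["g05", "k"] == 2


class TestForestRows:
    def test_single_study_combined_equals_study_row(self):
        det = make_detable(["g"], [1.0], t_mod=[2.0], n1=5, n2=5, df_total=10.0)
        meta = meta_analyze([det])
        rows = forest_rows(meta, "g")
        assert len(rows) == 2
        np.testing.assert_allclose(
            rows.iloc[0][["estimate", "ci_low", "ci_high"]].astype(float),
            rows.iloc[1][["estimate", "ci_low", "ci_high"]].astype(float),
        )

    def test_combined_ci_no_wider_than_any_study_with_equal_variances(self, rng):
        dets = [
            make_detable(["g"], [fc], t_mod=[fc / 0.6], study_id=s)
            for s, fc in zip("ab", [1.0, 1.2])
        ]
        meta = meta_analyze(dets)
        rows = forest_rows(meta, "g")
        widths = rows["ci_high"] - rows["ci_low"]
        assert widths.iloc[-1] <= widths.iloc[:-1].min() + 1e-12

    def test_rows_roundtrip_through_tsv(self, rng, tmp_path):
        dets = _three_studies(rng, n_genes=5)
        meta = meta_analyze(dets)
        rows = forest_rows(meta, "g00")
        path = tmp_path / "forest.tsv"
        rows.to_csv(path, sep="\t", index=False)
        back = pd.read_csv(path, sep="\t")
        pd.testing.assert_frame_equal(back, rows)

    def test_unknown_gene_errors(self, rng):
        meta = meta_analyze(_three_studies(rng, n_genes=5))
        with pytest.raises(ValidationError, match="unknown gene"):
            forest_rows(meta, "nope")


class TestMetaSignificant:
    def test_direction_split_sums_to_total(self):
        # 17 promoted (fc<0 under loss-of-function) + 23 inhibited = 40;
        # effects strong enough that the combined normal p survives BH
        genes = [f"g{i:02d}" for i in range(60)]
        fc = np.r_[-np.full(17, 3.0), np.full(23, 3.0), np.full(20, 0.1)]
        s2_post = np.r_[np.full(40, 0.04), np.full(20, 1.0)]
        det = make_detable(genes, fc, s2_post=s2_post)
        meta = meta_analyze([det])
        sig = meta_significant(meta, alpha_adj=0.05)
        counts = sig["direction"].value_counts()
        assert counts["promoted"] == 17
        assert counts["inhibited"] == 23
        assert len(sig) == 40

    def test_fc_gate_filters(self):
        det = make_detable(["a", "b"], [0.4, 1.2], s2_post=0.0004)
        meta = meta_analyze([det])
        assert len(meta_significant(meta)) == 2
        assert len(meta_significant(meta, fc_gate=1.5)) == 1

    def test_empty_table(self):
        det = make_detable(["a"], [1.0], p=[0.9])
        meta = meta_analyze([det])
        assert len(meta_significant(meta)) == 0


def test_fixed_and_dl_match_metafor(tmp_path, rng):
    """Independent cross-check against the R meta-analysis reference."""
    d = rng.normal(0.5, 1, 6)
    v = rng.uniform(0.1, 1.0, 6)
    pd.DataFrame({"yi": d, "vi": v}).to_csv(tmp_path / "dat.tsv", sep="\t", index=False)
    rscript = textwrap.dedent("""
        suppressMessages(library(metafor))
        dat <- read.delim("dat.tsv")
        fe <- rma(yi, vi, data=dat, method="FE")
        dl <- rma(yi, vi, data=dat, method="DL")
        write.table(data.frame(b_fe=fe$b, se_fe=fe$se, z_fe=fe$zval,
                               b_dl=dl$b, se_dl=dl$se, tau2=dl$tau2),
                    "ref.tsv", sep="\\t", row.names=FALSE, quote=FALSE)
    """)
    (tmp_path / "run.R").write_text(rscript)
    subprocess.run(["Rscript", "run.R"], cwd=tmp_path, check=True, capture_output=True)
    ref = pd.read_csv(tmp_path / "ref.tsv", sep="\t").iloc[0]

    es = pd.DataFrame({"study_id": [f"s{i}" for i in range(6)], "d": d, "var_d": v},
                      index=["g"] * 6)
    out = combine_effect_sizes(es)
    assert out.loc["g", "d_comb"] == pytest.approx(ref["b_fe"], rel=1e-6)
    assert out.loc["g", "se_comb"] == pytest.approx(ref["se_fe"], rel=1e-6)
    assert out.loc["g", "z"] == pytest.approx(ref["z_fe"], rel=1e-6)

    fcs = pd.DataFrame({"study_id": [f"s{i}" for i in range(6)], "log2fc": d,
                        "se": np.sqrt(v)}, index=["g"] * 6)
    dl = combine_fold_changes(fcs, method="random")
    assert dl.loc["g", "tau2"] == pytest.approx(ref["tau2"], rel=1e-6, abs=1e-10)
    assert dl.loc["g", "fc_comb"] == pytest.approx(ref["b_dl"], rel=1e-6)
    assert dl.loc["g", "fc_se"] == pytest.approx(ref["se_dl"], rel=1e-6)
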