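"""Size factors, differential expression, 2^-ddCt and translation efficiency."""

import numpy as np
import pandas as pd
import pytest

from ncrbp import diffexpr
from ncrbp.config import SimConfig
from ncrbp.synthetic import gen_expression_counts


def _counts(data, samples=None):
    df = pd.DataFrame(data)
    if samples:
        df.columns = samples
    df.index = [f"g{i}" for i in range(len(df))]
    df.index.name = "gene_id"
    return df


def _meta(groups, fractions=None):
    return pd.DataFrame(
        {
            "sample": list(groups),
            "group": list(groups.values()),
            "fraction": [fractions[s] for s in groups] if fractions else "total",
        }
    )


class TestSizeFactors:
    def test_identical_samples_get_unit_factors(self):
        counts = _counts({"a": [10, 20, 30], "b": [10, 20, 30]})
        np.testing.assert_allclose(diffexpr.size_factors(counts), 1.0)

    def test_doubled_sample_splits_factor_symmetrically(self):
        counts = _counts({"a": [10, 20, 40], "b": [20, 40, 80]})
        f = diffexpr.size_factors(counts)
        np.testing.assert_allclose(f, [1 / np.sqrt(2), np.sqrt(2)])

    def test_gene_with_a_zero_is_excluded_from_reference(self):
        counts = _counts({"a": [10, 20, 40], "b": [20, 40, 80]})
        with_zero = pd.concat(
            [counts, pd.DataFrame({"a": [1000], "b": [0]}, index=["gz"])]
        )
        np.testing.assert_allclose(
            diffexpr.size_factors(with_zero), diffexpr.size_factors(counts)
        )

    def test_scaling_one_sample_scales_its_relative_factor(self):
        # the geometric-mean reference rescales with the data, so equivariance
        # holds on factor ratios (the quantity normalization actually uses)
        counts = _counts({"a": [10, 21, 43], "b": [9, 33, 50], "c": [15, 18, 60]})
        base = diffexpr.size_factors(counts)
        scaled = counts.copy()
        scaled["b"] = scaled["b"] * 3
        f = diffexpr.size_factors(scaled)
        assert (f["b"] / f["a"]) / (base["b"] / base["a"]) == pytest.approx(3.0)
        assert f["c"] / f["a"] == pytest.approx(base["c"] / base["a"])

    def test_no_reference_genes_errors(self):
        counts = _counts({"a": [0, 5], "b": [5, 0]})
        with pytest.raises(ValueError, match="total-count"):
            diffexpr.size_factors(counts)

    def test_agrees_with_deseq2_reference_implementation(self):
        pydeseq2 = pytest.importorskip("pydeseq2")
        from pydeseq2.dds import DeseqDataSet

        cfg = SimConfig(seed=21, n_genes=300, include_rnc=False)
        counts, meta = gen_expression_counts(cfg)
        ours = diffexpr.size_factors(counts)
        dds = DeseqDataSet(
            counts=counts.T.astype(int),
            metadata=meta.set_index("sample")[["group"]].rename(columns={"group": "condition"}),
            design="~condition", quiet=True,
        )
        dds.fit_size_factors()
        np.testing.assert_allclose(ours.values, dds.obs["size_factors"].values, rtol=1e-6)


class TestDifferentialExpression:
    def test_identical_groups_score_zero_with_p_one(self):
        counts = _counts({"k1": [10, 50], "k2": [10, 50], "c1": [10, 50], "c2": [10, 50]})
        meta = _meta({"k1": "knockdown", "k2": "knockdown", "c1": "control", "c2": "control"})
        res = diffexpr.differential_expression(counts, meta)
        np.testing.assert_allclose(res["log2fc"], 0.0)
        np.testing.assert_allclose(res["p"], 1.0)

    def test_fourfold_mean_shift_approaches_two(self):
        # equal library compositions so size factors stay 1; large counts
        # make the 0.5 pseudocount negligible
        counts = _counts({
            "k1": [40000, 10000], "k2": [40000, 10000],
            "c1": [10000, 40000], "c2": [10000, 40000],
        })
        meta = _meta({"k1": "knockdown", "k2": "knockdown", "c1": "control", "c2": "control"})
        res = diffexpr.differential_expression(counts, meta)
        assert res.loc["g0", "log2fc"] == pytest.approx(2.0, abs=1e-3)

    def test_bh_adjustment_by_hand(self):
        from statsmodels.stats.multitest import multipletests
        padj = multipletests([0.01, 0.02, 0.03], method="fdr_bh")[1]
        np.testing.assert_allclose(padj, [0.03, 0.03, 0.03])
        counts = _counts({f"{g}{i}": np.arange(1, 6) * 10 for g in "kc" for i in (1, 2)})
        meta = _meta({"k1": "knockdown", "k2": "knockdown", "c1": "control", "c2": "control"})
        res = diffexpr.differential_expression(counts, meta)
        assert (res["padj"] >= res["p"] - 1e-15).all()
        assert (res["padj"] <= 1.0).all()

    def test_permuting_group_labels_flips_lfc_signs(self):
        cfg = SimConfig(seed=8, n_genes=80, include_rnc=False)
        counts, meta = gen_expression_counts(cfg)
        meta = meta[meta["fraction"] == "total"]
        res = diffexpr.differential_expression(counts, meta)
        flipped = meta.assign(group=meta["group"].map(
            {"control": "knockdown", "knockdown": "control"}))
        res_f = diffexpr.differential_expression(counts, flipped)
        np.testing.assert_allclose(res["log2fc"], -res_f["log2fc"], atol=1e-12)
        np.testing.assert_allclose(res["p"], res_f["p"], atol=1e-12)

    def test_single_sample_group_reports_lfc_without_p(self):
        counts = _counts({"k1": [10, 50], "c1": [20, 50]})
        meta = _meta({"k1": "knockdown", "c1": "control"})
        res = diffexpr.differential_expression(counts, meta)
        assert np.isfinite(res["log2fc"]).all()
        assert res["p"].isna().all()


class TestDdct:
    def test_equal_cts_give_unity(self):
        assert diffexpr.ddct(20, 20, 20, 20) == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "cts,expected",
        [((21, 10, 20, 10), 0.5),      # ddCt = +1
         ((20, 10, 22, 10), 4.0)],     # ddCt = -2
    )
    def test_hand_computed_relative_expression(self, cts, expected):
        assert diffexpr.ddct(*cts) == pytest.approx(expected)

    def test_missing_ct_errors(self):
        with pytest.raises(ValueError, match="missing"):
            diffexpr.ddct(20, np.nan, 20, 20)


class TestTranslationEfficiency:
    @staticmethod
    def _te_setup(kd_rnc_scale=1.0):
        # only gene g0 changes, so median-of-ratios factors stay at 1 and the
        # injected per-gene TE shift is not absorbed as a library-size effect
        samples = {}
        fractions = {}
        groups = {}
        for g in ("knockdown", "control"):
            for fr in ("RNC", "total"):
                for r in (1, 2):
                    name = f"{g}_{fr}_{r}"
                    base = np.array([1000.0, 2000.0, 500.0, 1500.0, 800.0])
                    if fr == "RNC" and g == "knockdown":
                        base = base.copy()
                        base[0] = base[0] * kd_rnc_scale
                    samples[name] = base
                    fractions[name] = fr
                    groups[name] = g
        counts = _counts(samples)
        meta = pd.DataFrame({"sample": list(samples), "group": [groups[s] for s in samples],
                             "fraction": [fractions[s] for s in samples]})
        return counts, meta

    def test_equal_fractions_give_unit_te_and_zero_shift(self):
        counts, meta = self._te_setup(1.0)
        res = diffexpr.translation_efficiency(counts, meta)
        np.testing.assert_allclose(res["te_control"], 1.0, atol=1e-3)
        np.testing.assert_allclose(res["delta_log2_te"], 0.0, atol=1e-3)

    def test_doubled_rnc_gene_in_knockdown_shifts_its_te_by_one(self):
        counts, meta = self._te_setup(2.0)
        res = diffexpr.translation_efficiency(counts, meta)
        assert res.loc["g0", "delta_log2_te"] == pytest.approx(1.0, abs=2e-3)
        np.testing.assert_allclose(res["delta_log2_te"].drop("g0"), 0.0, atol=2e-3)

    def test_permuting_gene_order_permutes_results(self):
        counts, meta = self._te_setup(2.0)
        res = diffexpr.translation_efficiency(counts, meta)
        shuffled = counts.iloc[::-1]
        res_s = diffexpr.translation_efficiency(shuffled, meta)
        pd.testing.assert_frame_equal(res.sort_index(), res_s.sort_index())

    def test_missing_fraction_errors(self):
        counts, meta = self._te_setup()
        meta = meta[~((meta["group"] == "control") & (meta["fraction"] == "RNC"))]
        with pytest.raises(ValueError, match="lacks"):
            diffexpr.translation_efficiency(counts[list(meta["sample"])], meta)

    def test_te_invariant_to_library_size_between_fractions(self):
        counts, meta = self._te_setup(2.0)
        scaled = counts.copy()
        for s in meta[meta["fraction"] == "RNC"]["sample"]:
            scaled[s] = scaled[s] * 7
        res = diffexpr.translation_efficiency(counts, meta)
        res_s = diffexpr.translation_efficiency(scaled, meta)
        # invariant up to the 0.5 pseudocount, whose weight shifts with scale
        np.testing.assert_allclose(res["delta_log2_te"], res_s["delta_log2_te"], atol=1e-3)
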