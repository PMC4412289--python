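"""Hierarchical cis/trans classification: component tests, the category
truth table, and recovery on data with known architecture."""
import numpy as np
import pandas as pd
import pytest

from cistrans.induction import tmm_factors
from cistrans.io import aggregate_gene_allele_counts, filter_snps
from cistrans.regdiv import (
    classify,
    compare_conditions,
    f1_allelic_test,
    parental_de_test,
    ratio_comparison_test,
    run_cistrans,
)
from cistrans.simulate import SimConfig, simulate_dataset


class TestParentalDE:
    def test_equal_counts_equal_libraries_is_null(self):
        assert parental_de_test(100, 100, 1e6, 1e6) == pytest.approx(1.0, abs=0.1)

    def test_total_imbalance_closed_form(self):
        assert parental_de_test(100, 0, 1e6, 1e6) == pytest.approx(
            2 * 0.5**100, rel=1e-9
        )

    def test_counts_proportional_to_libraries_is_null(self):
        assert parental_de_test(200, 100, 2e6, 1e6) > 0.5

    def test_zero_total_skipped(self):
        assert parental_de_test(0, 0, 1e6, 1e6) is None


class TestF1Allelic:
    def test_balanced_alleles(self):
        assert f1_allelic_test(50, 50) == pytest.approx(1.0, abs=1e-12)

    def test_monoallelic_closed_form(self):
        assert f1_allelic_test(30, 0) == pytest.approx(2 * 0.5**30, rel=1e-9)

    def test_twofold_cis_at_coverage_100(self):
        assert f1_allelic_test(67, 33) < 0.001


class TestRatioComparison:
    def test_equal_ratios_is_null(self):
        assert ratio_comparison_test((80, 20), (80, 20)) > 0.9

    def test_different_ratios_detected(self):
        assert ratio_comparison_test((80, 20), (50, 50)) < 0.001

    def test_power_grows_with_coverage(self):
        ps = [
            ratio_comparison_test((60 * k, 40 * k), (45 * k, 55 * k))
            for k in (1, 2, 4, 8)
        ]
        assert all(a > b for a, b in zip(ps, ps[1:]))

    def test_degenerate_row_flagged(self):
        assert ratio_comparison_test((0, 0), (10, 10)) is None


class TestClassify:
    @pytest.mark.parametrize(
        "p,f1,t,same,expected",
        [
            (True, True, False, True, "cis"),
            (True, True, False, None, "cis"),
            (True, False, True, None, "trans"),
            (True, True, True, True, "cis_plus_trans"),
            (True, True, True, False, "cis_x_trans"),
            (False, True, True, None, "compensatory"),
            (False, False, False, None, "conserved"),
            (True, False, False, None, "ambiguous"),
            (False, True, False, None, "ambiguous"),
            (False, False, True, None, "ambiguous"),
            (True, True, True, None, "ambiguous"),  # undefined direction
        ],
    )
    def test_truth_table(self, p, f1, t, same, expected):
        assert classify(p, f1, t, same) == expected


@pytest.fixture(scope="module")
def recovery_run():
    """Poisson-sampled single-cross dataset with strong cis and trans
    effects at high coverage, classified under both conditions."""
    config = SimConfig(
        n_genes=400,
        strains=("B6", "CAST"),
        cross_fathers=("CAST",),
        library_size=500 * 400 / 3,
        library_size_cv=0.0,
        dispersion=0.0,
        baseline_log2_sd=0.0,
        f1_coverage=1000,
        frac_induced=0.0,
        frac_cis=0.20,
        frac_trans=0.20,
        frac_cis_and_trans=0.0,
        frac_compensatory=0.0,
        frac_cis_tm_only=0.1,
        frac_trans_tm_only=0.0,
        cis_effect_range=(1.0, 1.0),
        trans_effect_range=(1.0, 1.0),
        seed=31,
    )
    sim = simulate_dataset(config)
    sim.counts.norm_factors = tmm_factors(sim.counts)
    gac = aggregate_gene_allele_counts(filter_snps(sim.snps))
    calls = {
        cond: run_cistrans(sim.counts, gac, "xCAST", "CAST", cond)
        for cond in ("control", "TM")
    }
    return sim, calls


class TestRunCistrans:
    def test_cis_gene_recovery(self, recovery_run):
        sim, calls = recovery_run
        truth = sim.truth.regulatory.query(
            "cross=='xCAST' and condition=='control'"
        ).set_index("gene")
        merged = calls["control"].set_index("gene").join(truth, rsuffix="_t")
        cis_true = merged[merged["category_t"] == "cis"]
        assert (cis_true["category"] == "cis").mean() >= 0.9
        assert cis_true["cis_mag"].median() == pytest.approx(1.0, abs=0.15)
        assert cis_true["pct_cis"].median() > 0.8

    def test_trans_gene_recovery(self, recovery_run):
        sim, calls = recovery_run
        truth = sim.truth.regulatory.query(
            "cross=='xCAST' and condition=='control'"
        ).set_index("gene")
        merged = calls["control"].set_index("gene").join(truth, rsuffix="_t")
        trans_true = merged[merged["category_t"] == "trans"]
        assert (trans_true["category"] == "trans").mean() >= 0.85
        assert trans_true["trans_mag"].median() == pytest.approx(1.0, abs=0.2)

    def test_null_genes_conserved(self, recovery_run):
        sim, calls = recovery_run
        truth = sim.truth.regulatory.query(
            "cross=='xCAST' and condition=='control'"
        ).set_index("gene")
        merged = calls["control"].set_index("gene").join(truth, rsuffix="_t")
        null = merged[merged["category_t"] == "conserved"]
        assert (null["category"] == "conserved").mean() >= 0.99

    def test_missing_parental_samples_raise(self, recovery_run):
        sim, _ = recovery_run
        gac = aggregate_gene_allele_counts(filter_snps(sim.snps))
        with pytest.raises(ValueError, match="xCAST"):
            run_cistrans(sim.counts, gac, "xCAST", "PWK", "control")

    def test_magnitudes_invariant_to_allele_relabeling(self, recovery_run):
        _, calls = recovery_run
        row = calls["control"].iloc[0]
        from cistrans.regdiv import _log2_ratio

        cis_mag = abs(_log2_ratio(row["f1_maternal"], row["f1_paternal"]))
        cis_mag_swapped = abs(_log2_ratio(row["f1_paternal"], row["f1_maternal"]))
        assert cis_mag == pytest.approx(cis_mag_swapped, abs=1e-12)

    def test_pct_cis_bounded(self, recovery_run):
        _, calls = recovery_run
        pc = calls["control"]["pct_cis"].dropna()
        assert ((pc >= 0) & (pc <= 1)).all()


class TestCompareConditions:
    def test_patterns_from_constructed_calls(self):
        def call_frame(cats):
            return pd.DataFrame(
                {
                    "gene": list(cats),
                    "category": list(cats.values()),
                    "cis_mag": 1.0,
                    "trans_mag": 0.2,
                }
            )

        control = call_frame({"g1": "cis", "g2": "conserved", "g3": "cis"})
        tm = call_frame({"g1": "cis", "g2": "cis", "g3": "conserved"})
        pat = compare_conditions(control, tm)
        cis = pat[pat["effect_type"] == "cis"].set_index("gene")
        assert cis.loc["g1", "pattern"] == "both"
        assert cis.loc["g2", "pattern"] == "TM-only"
        assert cis.loc["g3", "pattern"] == "control-only"
        trans = pat[pat["effect_type"] == "trans"].set_index("gene")
        assert (trans["pattern"] == "neither").all()

    def test_tm_only_cis_architecture_recovered(self, recovery_run):
        sim, calls = recovery_run
        pat = compare_conditions(calls["control"], calls["TM"])
        t = sim.truth.regulatory[sim.truth.regulatory["cross"] == "xCAST"].pivot(
            index="gene", columns="condition", values="cis"
        )
        tm_only = set(t.index[(t["control"] == 0) & (t["TM"] != 0)])
        sub = pat[(pat["effect_type"] == "cis") & (pat["gene"].isin(tm_only))]
        assert len(sub) > 10
        assert (sub["pattern"] == "TM-only").mean() >= 0.85
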