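"""Normalization, QC, induction calling, strain effects and the
co-response network."""
import numpy as np
import pandas as pd
import pytest

from cistrans.induction import test_induction as run_induction
from cistrans.induction import (
    QCError,
    correlation_network,
    estimate_common_dispersion,
    fold_change_table,
    induced_gene_sets,
    qc_condition_outliers,
    strain_effect,
    tmm_factors,
)
from cistrans.io import GeneCountMatrix
from cistrans.simulate import SimConfig, simulate_dataset


def _matrix(counts, strains, conditions, replicates):
    samples = pd.DataFrame(
        {
            "strain": strains,
            "condition": conditions,
            "replicate": replicates,
        },
        index=counts.columns,
    )
    return GeneCountMatrix(counts=counts, samples=samples)


class TestTMM:
    def test_identical_samples_give_unit_factors(self, rng):
        base = rng.poisson(100, size=200)
        counts = pd.DataFrame(
            {"a": base, "b": base, "c": base, "d": base},
            index=[f"g{i}" for i in range(200)],
        )
        m = _matrix(counts, ["s"] * 4, ["control", "control", "TM", "TM"], [1, 2, 1, 2])
        f = tmm_factors(m)
        assert f.to_numpy() == pytest.approx(np.ones(4), abs=1e-9)

    def test_depth_difference_with_same_composition(self, rng):
        base = rng.poisson(200, size=300) + 1
        counts = pd.DataFrame(
            {"a": base, "b": base * 2, "c": base, "d": base},
            index=[f"g{i}" for i in range(300)],
        )
        m = _matrix(counts, ["s"] * 4, ["control", "control", "TM", "TM"], [1, 2, 1, 2])
        f = tmm_factors(m)
        # same composition: all factors equal after geometric-mean rescaling
        assert f.to_numpy() == pytest.approx(np.ones(4), abs=1e-9)
        m.norm_factors = f
        cpm = m.counts / m.effective_lib_sizes * 1e6
        assert cpm["a"].to_numpy() == pytest.approx(cpm["b"].to_numpy(), rel=1e-9)

    def test_geometric_mean_is_one(self, small_sim):
        f = tmm_factors(small_sim.counts)
        assert np.exp(np.mean(np.log(f))) == pytest.approx(1.0, abs=1e-12)


class TestQC:
    def test_clean_strain_has_no_outliers(self, small_sim):
        m = small_sim.counts
        m.norm_factors = tmm_factors(m)
        assert qc_condition_outliers(m, "B6") == []

    def test_mislabeled_sample_is_detected(self, small_sim):
        m = small_sim.counts
        ids_c = m.strain_samples("B6", "control")
        ids_t = m.strain_samples("B6", "TM")
        counts = m.counts.copy()
        # a "control" library that was actually stressed: clone a TM profile
        counts[ids_c[0]] = counts[ids_t[0]]
        bad = GeneCountMatrix(counts, m.samples.copy())
        removed = qc_condition_outliers(bad, "B6")
        assert removed == [ids_c[0]]

    def test_overlapping_conditions_yield_no_removal(self):
        config = SimConfig(
            n_genes=150,
            strains=("B6", "CAST"),
            cross_fathers=("CAST",),
            frac_induced=0.0,
            library_size=1e5,
            seed=33,
        )
        sim = simulate_dataset(config)
        assert qc_condition_outliers(sim.counts, "B6") == []

    def test_refuses_removal_below_two_replicates(self, small_sim):
        m = small_sim.counts
        ids_c = m.strain_samples("B6", "control")
        ids_t = m.strain_samples("B6", "TM")
        keep = ids_c[:2] + ids_t
        sub = m.subset_samples(keep)
        counts = sub.counts.copy()
        counts[ids_c[0]] = counts[ids_t[0]]
        bad = GeneCountMatrix(counts, sub.samples.copy())
        with pytest.raises(QCError, match="B6"):
            qc_condition_outliers(bad, "B6")


@pytest.fixture(scope="module")
def induced_sim():
    config = SimConfig(
        n_genes=300,
        strains=("B6", "CAST"),
        cross_fathers=("CAST",),
        frac_induced=0.05,
        induction_log2_range=(2.0, 2.0),
        frac_induction_het=0.0,
        induced_common_frac=1.0,
        induced_unique_frac=0.0,
        frac_cis=0.0,
        frac_trans=0.0,
        frac_cis_and_trans=0.0,
        frac_compensatory=0.0,
        frac_cis_tm_only=0.0,
        frac_trans_tm_only=0.0,
        library_size=3e5,
        seed=77,
    )
    sim = simulate_dataset(config)
    sim.counts.norm_factors = tmm_factors(sim.counts)
    return sim


class TestInductionCalling:
    def test_recovers_fourfold_induction(self, induced_sim):
        res = run_induction(induced_sim.counts, "B6").set_index("gene")
        truth = induced_sim.truth.induction.query("strain=='B6'").set_index("gene")
        induced = truth[truth["log2fc"] == 2.0].index
        sub = res.loc[induced]
        assert sub["log2fc"].mean() == pytest.approx(2.0, abs=0.15)
        assert (sub["q"] < 0.01).mean() > 0.95

    def test_null_type_one_error_rate(self):
        config = SimConfig(
            n_genes=400,
            strains=("B6", "CAST"),
            cross_fathers=("CAST",),
            frac_induced=0.0,
            frac_cis=0.0, frac_trans=0.0, frac_cis_and_trans=0.0,
            frac_compensatory=0.0, frac_cis_tm_only=0.0, frac_trans_tm_only=0.0,
            library_size=3e5,
            seed=88,
        )
        sim = simulate_dataset(config)
        sim.counts.norm_factors = tmm_factors(sim.counts)
        res = run_induction(sim.counts, "B6")
        assert (res["p"] < 0.05).mean() == pytest.approx(0.05, abs=0.04)
        assert res["log2fc"].mean() == pytest.approx(0.0, abs=0.05)

    def test_identical_conditions_give_null_result(self):
        counts = pd.DataFrame(
            {
                "a": [100, 50],
                "b": [101, 49],
                "c": [100, 50],
                "d": [101, 49],
            },
            index=["g1", "g2"],
        )
        m = _matrix(counts, ["s"] * 4, ["control", "control", "TM", "TM"], [1, 2, 1, 2])
        res = run_induction(m, "s", dispersion=0.0)
        assert res["log2fc"].abs().max() < 0.05
        assert (res["p"] > 0.9).all()

    def test_all_zero_gene_excluded(self):
        counts = pd.DataFrame(
            {"a": [100, 0], "b": [90, 0], "c": [200, 0], "d": [210, 0]},
            index=["g1", "gz"],
        )
        m = _matrix(counts, ["s"] * 4, ["control", "control", "TM", "TM"], [1, 2, 1, 2])
        res = run_induction(m, "s", dispersion=0.05).set_index("gene")
        assert not res.loc["gz", "tested"]
        assert not res.loc["gz", "induced"]

    def test_dispersion_estimate_tracks_truth(self, small_sim):
        m = small_sim.counts
        m.norm_factors = tmm_factors(m)
        groups = [
            m.strain_samples(s, c)
            for s in ("B6", "129", "CAST", "NOD")
            for c in ("control", "TM")
        ]
        est = estimate_common_dispersion(m, groups)
        assert est == pytest.approx(small_sim.config.dispersion, rel=0.4)


class TestSharingSpectrum:
    def _results(self, calls):
        out = {}
        for strain, genes in calls.items():
            out[strain] = pd.DataFrame(
                {"gene": list(genes), "induced": True}
            )
        return out

    def test_partition_labels(self):
        res = self._results(
            {
                "s1": {"common", "unique1", "pair"},
                "s2": {"common", "pair"},
                "s3": {"common"},
            }
        )
        spec = induced_gene_sets(res).set_index("gene")
        assert spec.loc["common", "sharing"] == "common"
        assert spec.loc["unique1", "sharing"] == "unique"
        assert spec.loc["pair", "sharing"] == "shared"

    def test_partition_is_disjoint_and_exhaustive(self, small_sim):
        m = small_sim.counts
        m.norm_factors = tmm_factors(m)
        results = {
            s: run_induction(m, s) for s in ("B6", "129", "CAST", "NOD")
        }
        spec = induced_gene_sets(results)
        union = set()
        for r in results.values():
            union |= set(r.loc[r["induced"], "gene"])
        assert set(spec["gene"]) == union
        assert spec["gene"].is_unique
        assert set(spec["sharing"]) <= {"unique", "shared", "common"}


class TestStrainEffect:
    def _fc(self, data):
        rows = []
        for gene, strains in data.items():
            for strain, vals in strains.items():
                for i, v in enumerate(vals):
                    rows.append((gene, strain, i + 1, v))
        return pd.DataFrame(rows, columns=["gene", "strain", "replicate", "log2fc"])

    def test_identical_fold_changes_not_significant(self):
        fc = self._fc({"g1": {"a": [1.0, 1.0], "b": [1.0, 1.0]}})
        out = strain_effect(fc)
        assert out.iloc[0]["F"] == 0.0
        assert not out.iloc[0]["significant"]

    def test_hand_computed_f_statistic(self):
        fc = self._fc({"g1": {"a": [1.0, 1.2], "b": [2.0, 2.2]}})
        out = strain_effect(fc)
        assert out.iloc[0]["F"] == pytest.approx(50.0, rel=1e-9)

    def test_insufficient_replicates_skipped(self):
        fc = self._fc({"g1": {"a": [1.0], "b": [2.0, 2.1]}})
        out = strain_effect(fc)
        assert not out.iloc[0]["tested"]

    def test_recovery_of_strain_specific_induction(self):
        # recovery is evaluated with tight replicates (cell-line replicates
        # of identical genotype), where replicate noise is small relative
        # to the simulated strain differences in induction
        config = SimConfig(
            n_genes=150,
            strains=("B6", "CAST", "129", "NOD"),
            cross_fathers=("CAST",),
            frac_induced=0.3,
            induced_common_frac=0.0,
            induced_unique_frac=1.0,
            induction_log2_range=(1.5, 2.5),
            frac_cis=0.0, frac_trans=0.0, frac_cis_and_trans=0.0,
            frac_compensatory=0.0, frac_cis_tm_only=0.0, frac_trans_tm_only=0.0,
            library_size=3e5,
            dispersion=0.01,
            seed=55,
        )
        sim = simulate_dataset(config)
        sim.counts.norm_factors = tmm_factors(sim.counts)
        fc = fold_change_table(sim.counts)
        out = strain_effect(fc).set_index("gene")
        truth = sim.truth.induction.pivot(index="gene", columns="strain", values="log2fc")
        hetero = truth.index[(truth.max(axis=1) - truth.min(axis=1)) >= 1.5]
        hits = out.loc[[g for g in hetero if g in out.index], "significant"]
        assert hits.mean() >= 0.9


class TestCorrelationNetwork:
    def test_coexpressed_pair_connected(self, rng):
        latent = rng.normal(0, 1, 12)
        fc = pd.DataFrame(
            {
                "gene": ["gA"] * 12 + ["gB"] * 12,
                "strain": list("abcdef") * 4,
                "replicate": [1, 1, 1, 1, 1, 1, 2, 2, 2, 2, 2, 2] * 2,
                "log2fc": np.concatenate(
                    [latent + rng.normal(0, 0.05, 12), latent + rng.normal(0, 0.05, 12)]
                ),
            }
        )
        edges = correlation_network(fc)
        assert len(edges) == 1
        assert edges.iloc[0]["rho"] > 0.9

    def test_null_edge_rate_near_alpha(self, rng):
        n_obs, n_genes = 12, 30
        fc_rows = []
        for g in range(n_genes):
            vals = rng.normal(size=n_obs)
            for i in range(n_obs):
                fc_rows.append((f"g{g}", f"s{i % 6}", i // 6 + 1, vals[i]))
        fc = pd.DataFrame(fc_rows, columns=["gene", "strain", "replicate", "log2fc"])
        edges = correlation_network(fc, alpha=0.05)
        n_pairs = n_genes * (n_genes - 1) / 2
        assert len(edges) / n_pairs == pytest.approx(0.05, abs=0.03)

    def test_single_gene_gives_empty_network(self):
        fc = pd.DataFrame(
            {
                "gene": ["g1"] * 4,
                "strain": list("abcd"),
                "replicate": [1] * 4,
                "log2fc": [0.1, 0.2, 0.3, 0.4],
            }
        )
        assert correlation_network(fc, ["g1"]).empty
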