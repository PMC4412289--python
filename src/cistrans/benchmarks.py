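"""Recovery benchmarks: fixed simulation protocols with known truth and
the metrics that measure how well each pipeline stage recovers it.

Every function here *computes* its numbers by running the pipeline on
freshly simulated data; nothing is cached or tabulated.  The recovery
protocols use Poisson count sampling (``dispersion=0``) and uniform
baseline abundance so that the exact binomial/Fisher machinery is
evaluated under its own sampling assumptions; the induction benchmark
runs on the default configuration, overdispersion included.  See the
methods note for the rationale.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from . import ase, induction, regdiv, shared, simulate
from .io import aggregate_gene_allele_counts, filter_snps

__all__ = [
    "worked_allelic_examples",
    "category_recovery_config",
    "category_recovery_metrics",
    "condition_recovery_config",
    "condition_recovery_metrics",
    "ase_null_config",
    "ase_null_metrics",
    "induction_recovery_metrics",
]

#: reference examples of stress-induced allele-specific expression in
#: B6xCAST MEFs: control maternal (B6) proportion and the two reported
#: allele-specific linear fold changes under tunicamycin
WORKED_EXAMPLES = {
    "Sesn2": {"prop_control": 0.40, "maternal_fold": 1.7, "paternal_fold": 4.3},
    "Snhg5": {"prop_control": 0.38, "maternal_fold": 4.4, "paternal_fold": 2.1},
}


def worked_allelic_examples() -> dict:
    """Reconstruct post-stress allelic states from the reference inputs.

    For each example gene, the total linear fold change and the
    post-treatment maternal proportion implied by the control proportion
    and the two allele-specific folds.
    """
    out = {}
    for gene, ex in WORKED_EXAMPLES.items():
        total, prop_tm = ase.reconstruct_stress_state(
            ex["prop_control"], ex["maternal_fold"], ex["paternal_fold"]
        )
        out[gene] = {
            "total_fold": total,
            "prop_maternal_tm_pct": 100.0 * prop_tm,
        }
    return out


def category_recovery_config(seed: int, n_genes: int = 2000) -> simulate.SimConfig:
    """Single-cross protocol for cis/trans category recovery.

    2,000 genes, pooled allelic coverage 500 per gene and condition,
    |log2 effects| = 1, Poisson parental counts matched to the same
    per-gene depth; 15% cis genes, 10% trans genes, the rest null.
    """
    return simulate.SimConfig(
        n_genes=n_genes,
        strains=("B6", "CAST"),
        cross_fathers=("CAST",),
        n_replicates=3,
        library_size=500 * n_genes / 3,
        library_size_cv=0.0,
        dispersion=0.0,
        baseline_log2_sd=0.0,
        f1_coverage=500,
        frac_induced=0.0,
        frac_cis=0.15,
        frac_trans=0.10,
        frac_cis_and_trans=0.0,
        frac_compensatory=0.0,
        frac_cis_tm_only=0.0,
        frac_trans_tm_only=0.0,
        cis_effect_range=(1.0, 1.0),
        trans_effect_range=(1.0, 1.0),
        seed=seed,
    )


def category_recovery_metrics(seed: int, n_genes: int = 2000) -> dict:
    """Classification recovery rates under the category protocol."""
    config = category_recovery_config(seed, n_genes)
    result = simulate.simulate_dataset(config)
    matrix = result.counts
    matrix.norm_factors = induction.tmm_factors(matrix)
    gac = aggregate_gene_allele_counts(filter_snps(result.snps))
    calls = regdiv.run_cistrans(matrix, gac, "xCAST", "CAST", "control")
    truth = result.truth.regulatory.query(
        "cross == 'xCAST' and condition == 'control'"
    ).set_index("gene")
    merged = calls.set_index("gene").join(truth, rsuffix="_true")
    out = {}
    for true_cat, key in (
        ("cis", "cis_recovery_pct"),
        ("trans", "trans_recovery_pct"),
    ):
        sub = merged[merged["category_true"] == true_cat]
        out[key] = 100.0 * float((sub["category"] == true_cat).mean())
        out[f"n_{true_cat}"] = int(len(sub))
    null = merged[merged["category_true"] == "conserved"]
    out["null_nonconserved_pct"] = 100.0 * float(
        (null["category"] != "conserved").mean()
    )
    out["n_null"] = int(len(null))
    called = merged[merged["category"].isin(["cis", "trans"])]
    n_cis_called = int((called["category"] == "cis").sum())
    out["fraction_cis_pct"] = (
        100.0 * n_cis_called / len(called) if len(called) else float("nan")
    )
    return out


def condition_recovery_config(seed: int, n_genes: int = 2000) -> simulate.SimConfig:
    """Five-cross protocol with condition-specific (TM-only) cis effects.

    Static cis effects are shared between crosses half the time; TM-only
    cis effects are always private to one cross, so stress dilutes
    cross-sharing by design.
    """
    return simulate.SimConfig(
        n_genes=n_genes,
        strains=("B6", "129", "NOD", "NZO", "WSB", "CAST"),
        cross_fathers=("129", "NOD", "NZO", "WSB", "CAST"),
        n_replicates=3,
        library_size=500 * n_genes / 3,
        library_size_cv=0.0,
        dispersion=0.0,
        baseline_log2_sd=0.0,
        f1_coverage=500,
        frac_induced=0.0,
        frac_cis=0.10,
        frac_trans=0.05,
        frac_cis_and_trans=0.0,
        frac_compensatory=0.0,
        frac_cis_tm_only=0.05,
        frac_trans_tm_only=0.0,
        cis_effect_range=(1.0, 1.0),
        trans_effect_range=(1.0, 1.0),
        frac_shared_effect=0.5,
        seed=seed,
    )


def condition_recovery_metrics(seed: int, n_genes: int = 2000) -> dict:
    """TM-only labeling rate and the stress-induced drop in sharing."""
    config = condition_recovery_config(seed, n_genes)
    result = simulate.simulate_dataset(config)
    matrix = result.counts
    matrix.norm_factors = induction.tmm_factors(matrix)
    gac = aggregate_gene_allele_counts(filter_snps(result.snps))
    truth = result.truth.regulatory
    calls: dict[tuple[str, str], pd.DataFrame] = {}
    for father in config.cross_fathers:
        cross = f"x{father}"
        for condition in ("control", "TM"):
            calls[(cross, condition)] = regdiv.run_cistrans(
                matrix, gac, cross, father, condition
            )
    tm_only_total = tm_only_hit = 0
    for father in config.cross_fathers:
        cross = f"x{father}"
        patterns = regdiv.compare_conditions(
            calls[(cross, "control")], calls[(cross, "TM")]
        )
        t = truth[truth["cross"] == cross].pivot(
            index="gene", columns="condition", values="cis"
        )
        tm_only_genes = set(t.index[(t["control"] == 0) & (t["TM"] != 0)])
        sub = patterns[
            (patterns["effect_type"] == "cis") & (patterns["gene"].isin(tm_only_genes))
        ]
        tm_only_total += len(sub)
        tm_only_hit += int((sub["pattern"] == "TM-only").sum())
    shared_by_cond = {
        condition: shared.find_shared(
            {f"x{f}": calls[(f"x{f}", condition)] for f in config.cross_fathers},
            "cis",
        )
        for condition in ("control", "TM")
    }
    contrast = shared.condition_sharing_contrast(
        shared_by_cond["control"], shared_by_cond["TM"]
    )
    return {
        "tm_only_cis_label_pct": 100.0 * tm_only_hit / tm_only_total
        if tm_only_total
        else float("nan"),
        "n_tm_only": int(tm_only_total),
        "shared_cis_control_pct": contrast["control"]["shared_pct"],
        "shared_cis_tm_pct": contrast["TM"]["shared_pct"],
        "n_cis_effect_genes_control": contrast["control"]["shared"]
        + contrast["control"]["unique"],
        "n_cis_effect_genes_tm": contrast["TM"]["shared"] + contrast["TM"]["unique"],
        "sharing_contrast_p": contrast["p"],
    }


def ase_null_config(seed: int, n_genes: int = 800) -> simulate.SimConfig:
    """Static architecture only: no condition-specific allelic shifts."""
    return simulate.SimConfig(
        n_genes=n_genes,
        strains=("B6", "CAST"),
        cross_fathers=("CAST",),
        library_size=1e6,
        f1_coverage=300,
        frac_induced=0.2,
        frac_cis=0.15,
        frac_trans=0.05,
        frac_cis_and_trans=0.0,
        frac_compensatory=0.0,
        frac_cis_tm_only=0.0,
        frac_trans_tm_only=0.0,
        seed=seed,
    )


def ase_null_metrics(seed: int, n_genes: int = 800) -> dict:
    """Fraction of informative genes with a significant ASE change when
    no gene's allelic proportion actually changes with treatment."""
    config = ase_null_config(seed, n_genes)
    result = simulate.simulate_dataset(config)
    gac = aggregate_gene_allele_counts(filter_snps(result.snps))
    res = ase.test_ase_change(gac, "xCAST")
    return {
        "ase_null_significant_pct": 100.0 * float(res["significant"].mean()),
        "n_informative": int(len(res)),
    }


def induction_recovery_metrics(outdir) -> dict:
    """Sensitivity and empirical FDR of induction calling, measured on a
    completed default-configuration pipeline run directory.

    Sensitivity: fraction of gene x strain pairs with net true log2 fold
    change >= log2(3) called induced.  Empirical FDR: fraction of induced
    calls whose net true fold change is <= 0 (no real upregulation).
    """
    from pathlib import Path

    import yaml

    outdir = Path(outdir)
    truth = pd.read_csv(outdir / "truth_induction.tsv", sep="\t", comment="#")
    config = yaml.safe_load((outdir / "config.yaml").read_text())
    n_called = n_false = n_strong = n_strong_called = 0
    for strain in config["simulation"]["strains"]:
        res = pd.read_csv(outdir / f"induction_{strain}.tsv", sep="\t", comment="#")
        t = truth[truth["strain"] == strain].set_index("gene")["log2fc"]
        merged = res.set_index("gene").join(t.rename("true_fc"))
        called = merged["induced"].fillna(False)
        strong = merged["true_fc"] >= np.log2(3)
        n_strong += int(strong.sum())
        n_strong_called += int((strong & called).sum())
        n_called += int(called.sum())
        n_false += int((called & (merged["true_fc"] <= 0)).sum())
    return {
        "induction_sensitivity_pct": 100.0 * n_strong_called / n_strong,
        "n_strong": int(n_strong),
        "induction_empirical_fdr_pct": 100.0 * n_false / n_called,
        "n_called": int(n_called),
    }
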