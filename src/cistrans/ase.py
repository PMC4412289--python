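"""Stress-induced changes in allele-specific expression (ASE).

Within an F1 cross, the maternal allelic proportion — maternal reads over
total allelic coverage of a transcript — is compared between control and
TM conditions with a Fisher exact test on the pooled allele counts,
followed by BH correction across genes.  A significant shift means the
two alleles respond differently to ER stress; it can occur with or
without a change in total transcript abundance.

The allelic fold decomposition splits a gene's total linear fold change
into per-allele fold changes:

    fold(allele) = total_fold * prop_allele(TM) / prop_allele(control)

with the consistency identity
``sum_allele prop_control(allele) * fold(allele) = total_fold``, which
also allows the post-stress allelic state to be reconstructed from a
control proportion and the two allele-specific folds.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .io import informative_genes
from .stats import bh_fdr, fisher_exact_two_sided

__all__ = [
    "ASE_FDR",
    "test_ase_change",
    "allelic_fold_decomposition",
    "reconstruct_stress_state",
    "summarize_ase",
]

#: default FDR threshold for a significant ASE change
ASE_FDR = 0.05


def test_ase_change(
    gac: pd.DataFrame, cross: str, fdr: float = ASE_FDR
) -> pd.DataFrame:
    """Test every informative gene of one cross for a TM-induced ASE shift.

    Genes must clear the ASE informativeness rule (>= 2 SNPs, pooled
    coverage > 50) in both conditions.  The test is Fisher's exact on the
    2x2 table [(maternal, paternal) control; (maternal, paternal) TM].
    Returns columns ``gene, cross, prop_maternal_control, prop_maternal_tm,
    p, q, significant, direction``.
    """
    info = informative_genes(gac, "ase").get(cross, frozenset())
    sub = gac[(gac["cross"] == cross) & (gac["gene"].isin(info))]
    wide = sub.pivot_table(
        index="gene",
        columns="condition",
        values=["maternal_total", "paternal_total"],
        aggfunc="first",
    )
    rows = []
    for gene in sorted(wide.index):
        mc = int(wide.loc[gene, ("maternal_total", "control")])
        pc = int(wide.loc[gene, ("paternal_total", "control")])
        mt = int(wide.loc[gene, ("maternal_total", "TM")])
        pt = int(wide.loc[gene, ("paternal_total", "TM")])
        prop_c = mc / (mc + pc)
        prop_t = mt / (mt + pt)
        p = fisher_exact_two_sided([[mc, pc], [mt, pt]])
        rows.append((gene, cross, prop_c, prop_t, p))
    out = pd.DataFrame(
        rows,
        columns=["gene", "cross", "prop_maternal_control", "prop_maternal_tm", "p"],
    )
    if out.empty:
        for col in ("q", "significant", "direction"):
            out[col] = pd.Series(dtype=object)
        return out
    out["q"] = bh_fdr(out["p"].to_numpy())
    out["significant"] = out["q"] <= fdr
    delta = out["prop_maternal_tm"] - out["prop_maternal_control"]
    out["direction"] = np.where(delta > 0, "maternal_up", np.where(delta < 0, "maternal_down", "none"))
    return out


def allelic_fold_decomposition(
    prop_maternal_control: float,
    prop_maternal_tm: float,
    total_fold: float,
) -> tuple[float, float]:
    """Split a total linear fold change into maternal and paternal folds.

    Returns ``(maternal_fold, paternal_fold)``.  A zero control proportion
    leaves the corresponding allele's fold undefined (NaN).
    """
    if not 0.0 <= prop_maternal_control <= 1.0 or not 0.0 <= prop_maternal_tm <= 1.0:
        raise ValueError("proportions must lie in [0, 1]")
    if total_fold <= 0:
        raise ValueError("total fold change must be positive")
    maternal = (
        total_fold * prop_maternal_tm / prop_maternal_control
        if prop_maternal_control > 0
        else float("nan")
    )
    paternal = (
        total_fold * (1 - prop_maternal_tm) / (1 - prop_maternal_control)
        if prop_maternal_control < 1
        else float("nan")
    )
    return maternal, paternal


def reconstruct_stress_state(
    prop_maternal_control: float,
    maternal_fold: float,
    paternal_fold: float,
) -> tuple[float, float]:
    """Invert the decomposition: recover total fold and TM proportion.

    Given the control maternal proportion and the two allele-specific
    linear folds, the total fold is their proportion-weighted mean and the
    TM maternal proportion is the maternal allele's share of it.
    """
    if not 0.0 < prop_maternal_control < 1.0:
        raise ValueError("control proportion must be strictly inside (0, 1)")
    if min(maternal_fold, paternal_fold) < 0:
        raise ValueError("allele folds must be non-negative")
    total = (
        prop_maternal_control * maternal_fold
        + (1 - prop_maternal_control) * paternal_fold
    )
    if total == 0:
        raise ValueError("both alleles fully silenced; proportion undefined")
    prop_tm = prop_maternal_control * maternal_fold / total
    return total, prop_tm


def summarize_ase(
    results_by_cross: dict[str, pd.DataFrame],
    induced_by_cross: dict[str, frozenset] | None = None,
) -> pd.DataFrame:
    """Per-cross summary of stress-induced ASE.

    For each cross: the number and percentage of informative genes with a
    significant ASE change, how many of those are also TM-upregulated
    (when induction calls are supplied), and the direction tallies of the
    maternal proportion shift.
    """
    rows = []
    for cross in sorted(results_by_cross):
        res = results_by_cross[cross]
        n_info = len(res)
        sig = res[res["significant"]] if n_info else res
        n_sig = int(len(sig))
        induced = (induced_by_cross or {}).get(cross)
        if induced is not None and n_sig:
            n_up = int(sig["gene"].isin(induced).sum())
        else:
            n_up = 0 if induced is not None else None
        rows.append(
            {
                "cross": cross,
                "n_informative": n_info,
                "ase_change_n": n_sig,
                "ase_change_pct": 100.0 * n_sig / n_info if n_info else 0.0,
                "upregulated_n": n_up,
                "upregulated_pct": (
                    100.0 * n_up / n_sig if n_up is not None and n_sig else
                    (0.0 if n_up is not None else None)
                ),
                "maternal_up": int((sig["direction"] == "maternal_up").sum()) if n_sig else 0,
                "maternal_down": int((sig["direction"] == "maternal_down").sum()) if n_sig else 0,
            }
        )
    return pd.DataFrame(rows)
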