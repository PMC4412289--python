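"""Hierarchical cis/trans classification of regulatory divergence.

For one F1 cross and one condition, three exact tests are combined per
gene:

1. parental differential expression — binomial exact test of the pooled
   maternal-strain count against the two strains' effective library sizes;
2. F1 allelic imbalance — binomial exact test of pooled maternal allele
   counts against 0.5 (both alleles share one trans environment, so
   imbalance isolates cis effects);
3. ratio comparison (the trans test) — Fisher exact test of the parental
   ratio against the F1 allelic ratio, applied only to genes significant
   in step 1; a significant difference in ratios indicates trans
   regulation.

BH correction is applied within each test family (step 2 within the
tested subset), all at a conservative FDR (0.1% by default), and the
significance pattern maps to one of seven categories: cis, trans,
cis_plus_trans, cis_x_trans, compensatory, conserved, ambiguous.
Magnitudes are |log2 F1 allelic ratio| (cis) and |log2 parental ratio -
log2 F1 allelic ratio| (trans); %cis is their normalized share.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .io import GeneCountMatrix, informative_genes
from .stats import bh_fdr, binomial_exact_two_sided, fisher_exact_two_sided

__all__ = [
    "CISTRANS_FDR",
    "parental_de_test",
    "f1_allelic_test",
    "ratio_comparison_test",
    "classify",
    "run_cistrans",
    "compare_conditions",
    "summarize_calls",
]

#: default FDR threshold applied at every level of the hierarchy
CISTRANS_FDR = 0.001


def parental_de_test(
    count_a: int, count_b: int, lib_a: float, lib_b: float
) -> float | None:
    """Binomial exact test of differential expression between two strains.

    ``count_a``/``count_b`` are replicate-pooled gene counts; the null
    success probability is the share of strain A in the combined effective
    library.  Returns ``None`` (gene skipped) when both counts are zero.
    """
    if min(count_a, count_b) < 0 or min(lib_a, lib_b) <= 0:
        raise ValueError("counts must be >= 0 and library sizes > 0")
    total = count_a + count_b
    if total == 0:
        return None
    return binomial_exact_two_sided(count_a, total, lib_a / (lib_a + lib_b))


def f1_allelic_test(maternal_total: int, paternal_total: int) -> float:
    """Binomial exact test of F1 allelic imbalance against a 0.5 null."""
    total = maternal_total + paternal_total
    return binomial_exact_two_sided(maternal_total, total, 0.5)


def ratio_comparison_test(
    parental: tuple[int, int], f1: tuple[int, int]
) -> float | None:
    """Fisher exact test comparing parental and F1 allelic ratios.

    ``parental`` must already be standardized to a common library size.
    Returns ``None`` when a row is empty (degenerate; flagged ambiguous).
    """
    a, b = parental
    m, p = f1
    if a + b == 0 or m + p == 0:
        return None
    return fisher_exact_two_sided([[a, b], [m, p]])


def classify(
    p_sig: bool,
    f1_sig: bool,
    trans_sig: bool,
    direction_same: bool | None = None,
) -> str:
    """Map the three significance calls (and ratio-direction agreement)
    onto the seven-category scheme."""
    pattern = (p_sig, f1_sig, trans_sig)
    if pattern == (True, True, False):
        return "cis"
    if pattern == (True, False, True):
        return "trans"
    if pattern == (True, True, True):
        if direction_same is None:
            return "ambiguous"
        return "cis_plus_trans" if direction_same else "cis_x_trans"
    if pattern == (False, True, True):
        return "compensatory"
    if pattern == (False, False, False):
        return "conserved"
    return "ambiguous"


def _log2_ratio(a: float, b: float) -> float:
    return float(np.log2((a + 0.5) / (b + 0.5)))


def run_cistrans(
    matrix: GeneCountMatrix,
    gac: pd.DataFrame,
    cross: str,
    father: str,
    condition: str,
    fdr: float = CISTRANS_FDR,
    maternal_strain: str | None = None,
) -> pd.DataFrame:
    """Classify regulatory divergence for every informative gene of one
    cross under one condition.

    ``matrix`` is the normalized (TMM) parental panel; ``gac`` the pooled
    gene-level allelic counts.  Parental counts entering the Fisher table
    are standardized to the mean of the two effective library sizes and
    rounded.  Conditions are always analyzed separately.
    """
    maternal_strain = maternal_strain or matrix.samples["strain"].iloc[0]
    info = informative_genes(gac, "cistrans", condition=condition).get(
        cross, frozenset()
    )
    ids_m = matrix.strain_samples(maternal_strain, condition)
    ids_p = matrix.strain_samples(father, condition)
    if not ids_m or not ids_p:
        raise ValueError(
            f"missing parental samples for cross {cross!r} "
            f"({maternal_strain} x {father}, {condition})"
        )
    pooled_m = matrix.counts[ids_m].sum(axis=1)
    pooled_p = matrix.counts[ids_p].sum(axis=1)
    lib_m = float(matrix.effective_lib_sizes.loc[ids_m].sum())
    lib_p = float(matrix.effective_lib_sizes.loc[ids_p].sum())
    lib_bar = 0.5 * (lib_m + lib_p)

    sub = gac[
        (gac["cross"] == cross)
        & (gac["condition"] == condition)
        & (gac["gene"].isin(info))
    ].set_index("gene")
    genes = sorted(g for g in sub.index if g in pooled_m.index)

    rows = []
    for gene in genes:
        cm = int(pooled_m.loc[gene])
        cp = int(pooled_p.loc[gene])
        m1 = int(sub.loc[gene, "maternal_total"])
        p1 = int(sub.loc[gene, "paternal_total"])
        p_par = parental_de_test(cm, cp, lib_m, lib_p)
        if p_par is None:
            continue
        p_f1 = f1_allelic_test(m1, p1)
        a = int(round(cm * lib_bar / lib_m))
        b = int(round(cp * lib_bar / lib_p))
        sign_p = float(np.sign(_log2_ratio(a, b)))
        sign_f1 = float(np.sign(_log2_ratio(m1, p1)))
        cis_mag = abs(_log2_ratio(m1, p1))
        trans_mag = abs(_log2_ratio(a, b) - _log2_ratio(m1, p1))
        rows.append(
            {
                "gene": gene,
                "cross": cross,
                "condition": condition,
                "parental_maternal": cm,
                "parental_paternal": cp,
                "parental_maternal_std": a,
                "parental_paternal_std": b,
                "f1_maternal": m1,
                "f1_paternal": p1,
                "p_P": p_par,
                "p_F1": p_f1,
                "sign_P": sign_p,
                "sign_F1": sign_f1,
                "cis_mag": cis_mag,
                "trans_mag": trans_mag,
            }
        )
    calls = pd.DataFrame(rows)
    if calls.empty:
        return calls
    calls["q_P"] = bh_fdr(calls["p_P"].to_numpy())
    calls["q_F1"] = bh_fdr(calls["p_F1"].to_numpy())
    sig_p = calls["q_P"] <= fdr
    sig_f1 = calls["q_F1"] <= fdr
    step2 = (sig_p | sig_f1).to_numpy()

    p_t = np.full(len(calls), np.nan)
    degenerate = np.zeros(len(calls), dtype=bool)
    for i in np.flatnonzero(step2):
        row = calls.iloc[i]
        res = ratio_comparison_test(
            (int(row["parental_maternal_std"]), int(row["parental_paternal_std"])),
            (int(row["f1_maternal"]), int(row["f1_paternal"])),
        )
        if res is None:
            degenerate[i] = True
        else:
            p_t[i] = res
    calls["p_T"] = p_t
    q_t = np.full(len(calls), np.nan)
    tested = step2 & ~degenerate
    if tested.any():
        q_t[tested] = bh_fdr(p_t[tested])
    calls["q_T"] = q_t
    sig_t = pd.Series(tested & (q_t <= fdr), index=calls.index).fillna(False)

    categories = []
    for i in range(len(calls)):
        if degenerate[i]:
            categories.append("ambiguous")
            continue
        same: bool | None
        if calls["sign_P"].iat[i] == 0 or calls["sign_F1"].iat[i] == 0:
            same = None
        else:
            same = calls["sign_P"].iat[i] == calls["sign_F1"].iat[i]
        categories.append(
            classify(bool(sig_p.iat[i]), bool(sig_f1.iat[i]), bool(sig_t.iat[i]), same)
        )
    calls["category"] = categories
    denom = calls["cis_mag"] + calls["trans_mag"]
    calls["pct_cis"] = np.where(denom > 0, calls["cis_mag"] / denom, np.nan)
    return calls


def compare_conditions(
    calls_control: pd.DataFrame, calls_tm: pd.DataFrame
) -> pd.DataFrame:
    """Per-gene condition dependence of cis/trans calls for one cross.

    For every gene informative in both conditions and each effect type,
    labels the call pattern ``both`` / ``control-only`` / ``TM-only`` /
    ``neither`` and carries the two magnitudes (paired for ``both``
    genes, the correlation input for condition-stability summaries).
    """
    merged = calls_control.merge(
        calls_tm, on="gene", suffixes=("_control", "_tm"), how="inner"
    )
    rows = []
    for effect in ("cis", "trans"):
        mag_col = f"{effect}_mag"
        for _, row in merged.iterrows():
            in_c = row["category_control"] == effect
            in_t = row["category_tm"] == effect
            if in_c and in_t:
                pattern = "both"
            elif in_c:
                pattern = "control-only"
            elif in_t:
                pattern = "TM-only"
            else:
                pattern = "neither"
            rows.append(
                (
                    row["gene"],
                    effect,
                    pattern,
                    row[f"{mag_col}_control"],
                    row[f"{mag_col}_tm"],
                )
            )
    return pd.DataFrame(
        rows, columns=["gene", "effect_type", "pattern", "mag_control", "mag_tm"]
    )


def summarize_calls(calls: pd.DataFrame) -> dict:
    """Category counts and magnitude medians for one cross x condition."""
    if calls.empty:
        return {"n_informative": 0, "categories": {}}
    counts = calls["category"].value_counts().to_dict()
    n_cis = counts.get("cis", 0)
    n_trans = counts.get("trans", 0)
    cis_rows = calls[calls["category"] == "cis"]
    trans_rows = calls[calls["category"] == "trans"]
    either = calls[calls["category"].isin(["cis", "trans"])]
    return {
        "n_informative": int(len(calls)),
        "categories": {k: int(v) for k, v in sorted(counts.items())},
        "n_regulatory_differences": int(n_cis + n_trans),
        "fraction_cis": float(n_cis / (n_cis + n_trans)) if n_cis + n_trans else None,
        "median_cis_magnitude": float(cis_rows["cis_mag"].median()) if len(cis_rows) else None,
        "median_trans_magnitude": float(trans_rows["trans_mag"].median()) if len(trans_rows) else None,
        "median_pct_cis": float(either["pct_cis"].median()) if len(either) else None,
    }
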