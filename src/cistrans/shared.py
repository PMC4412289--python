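"""Shared regulatory differences across F1 crosses.

Because all crosses share the maternal strain, a gene showing the same
type of regulatory difference (cis with cis, trans with trans) in two or
more crosses points to paternal strains diverging from the reference in
the same way.  Sharing requires the gene to be informative in at least
two crosses.  For shared cis differences, heterogeneity of the allelic
magnitude across the sharing crosses (a strain effect) is tested by
Pearson chi-squared on the pooled maternal/paternal counts, BH-corrected
at 5% FDR.  The control-vs-TM contrast of sharing proportions is a 2x2
chi-squared test.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .stats import DegenerateTableError, bh_fdr, chi2_heterogeneity

__all__ = [
    "SHARED_FDR",
    "find_shared",
    "strain_effect_on_shared",
    "condition_sharing_contrast",
]

#: FDR threshold for the chi-squared strain effect on shared differences
SHARED_FDR = 0.05


def find_shared(
    calls_by_cross: dict[str, pd.DataFrame], effect_type: str
) -> pd.DataFrame:
    """Tabulate sharing of one effect type across crosses (one condition).

    A gene enters the table when informative in >= 2 crosses and carrying
    the effect in >= 1; ``shared`` means the same category in >= 2
    crosses.  Sharing is category-based, not direction-based: opposite-
    direction cis differences still count as shared (direction
    concordance is reported separately as ``n_direction_concordant``).
    """
    if effect_type not in ("cis", "trans"):
        raise ValueError("effect_type must be 'cis' or 'trans'")
    crosses = sorted(calls_by_cross)
    per_gene: dict[str, dict] = {}
    for cross in crosses:
        calls = calls_by_cross[cross]
        for _, row in calls.iterrows():
            rec = per_gene.setdefault(
                row["gene"], {c: None for c in crosses}
            )
            rec[cross] = (row["category"], row["sign_F1"])
    rows = []
    for gene in sorted(per_gene):
        rec = per_gene[gene]
        informative = [c for c in crosses if rec[c] is not None]
        if len(informative) < 2:
            continue
        with_effect = [c for c in informative if rec[c][0] == effect_type]
        if not with_effect:
            continue
        signs = [rec[c][1] for c in with_effect]
        concordant = len(set(np.sign(signs))) == 1 if signs else False
        rows.append(
            {
                "gene": gene,
                "effect_type": effect_type,
                "n_informative_crosses": len(informative),
                "n_crosses_with_effect": len(with_effect),
                "crosses_with_effect": ";".join(with_effect),
                "shared": len(with_effect) >= 2,
                "n_direction_concordant": int(concordant),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene",
            "effect_type",
            "n_informative_crosses",
            "n_crosses_with_effect",
            "crosses_with_effect",
            "shared",
            "n_direction_concordant",
        ],
    )


def strain_effect_on_shared(
    shared: pd.DataFrame,
    gac: pd.DataFrame,
    condition: str,
    fdr: float = SHARED_FDR,
) -> pd.DataFrame:
    """Chi-squared heterogeneity of allelic magnitude across sharing crosses.

    For every shared gene, builds the K x 2 table of pooled maternal and
    paternal counts over the crosses that carry the effect and tests
    homogeneity of the allelic proportion.  Operating on counts (rather
    than ratio estimates) keeps the test exact-sampling based.  Genes with
    degenerate tables are flagged untestable.
    """
    pool = gac[gac["condition"] == condition].set_index(["gene", "cross"])
    out = shared.copy()
    stats = np.full(len(out), np.nan)
    pvals = np.full(len(out), np.nan)
    testable = np.zeros(len(out), dtype=bool)
    for i, row in enumerate(out.itertuples(index=False)):
        if not row.shared:
            continue
        table = []
        for cross in row.crosses_with_effect.split(";"):
            try:
                rec = pool.loc[(row.gene, cross)]
            except KeyError:
                continue
            table.append([rec["maternal_total"], rec["paternal_total"]])
        if len(table) < 2:
            continue
        try:
            stats[i], pvals[i] = chi2_heterogeneity(table)
            testable[i] = True
        except (DegenerateTableError, ValueError):
            continue
    out["chi2_stat"] = stats
    out["p"] = pvals
    q = np.full(len(out), np.nan)
    if testable.any():
        q[testable] = bh_fdr(pvals[testable])
    out["q"] = q
    out["testable"] = testable
    out["strain_effect"] = testable & (out["q"] <= fdr)
    return out


def condition_sharing_contrast(
    shared_control: pd.DataFrame, shared_tm: pd.DataFrame
) -> dict:
    """Contrast sharing proportions between control and TM conditions.

    Counts shared vs unique genes (among genes with the effect, informative
    in >= 2 crosses) per condition and tests the proportion difference with
    a 2x2 Pearson chi-squared; also stratifies by the number of informative
    crosses.  Within each condition shared + unique equals the number of
    genes carrying the effect.
    """

    def tally(frame: pd.DataFrame) -> tuple[int, int]:
        n_shared = int(frame["shared"].sum())
        return n_shared, int(len(frame) - n_shared)

    s_c, u_c = tally(shared_control)
    s_t, u_t = tally(shared_tm)
    result = {
        "control": {"shared": s_c, "unique": u_c,
                    "shared_pct": 100.0 * s_c / (s_c + u_c) if s_c + u_c else None},
        "TM": {"shared": s_t, "unique": u_t,
               "shared_pct": 100.0 * s_t / (s_t + u_t) if s_t + u_t else None},
    }
    try:
        stat, p = chi2_heterogeneity([[s_c, u_c], [s_t, u_t]])
        result["chi2_stat"], result["p"] = stat, p
    except (DegenerateTableError, ValueError):
        result["chi2_stat"] = result["p"] = None
    strata = {}
    for k in sorted(
        set(shared_control["n_informative_crosses"]).union(
            shared_tm["n_informative_crosses"]
        )
    ):
        sc = shared_control[shared_control["n_informative_crosses"] == k]
        st = shared_tm[shared_tm["n_informative_crosses"] == k]
        s1, u1 = tally(sc)
        s2, u2 = tally(st)
        entry = {"control": {"shared": s1, "unique": u1},
                 "TM": {"shared": s2, "unique": u2}}
        try:
            stat, p = chi2_heterogeneity([[s1, u1], [s2, u2]])
            entry["p"] = p
        except (DegenerateTableError, ValueError):
            entry["p"] = None
        strata[int(k)] = entry
    result["by_n_informative"] = strata
    return result
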