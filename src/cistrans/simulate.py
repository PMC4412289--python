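"""Synthetic data with a known regulatory architecture.

The generator emulates the structure of an F1-hybrid ER-stress experiment:
a panel of inbred strains (the maternal reference strain first) assayed in
control and tunicamycin (TM) conditions with replicate libraries, plus a
set of F1 crosses sharing the maternal strain.  Per gene it draws

* a baseline relative abundance (log-normal across genes),
* strain-specific TM induction effects (log2 fold changes),
* cis effects ``c`` — log2 maternal/paternal allelic ratios that appear
  both in the F1 allelic ratio and the parental expression ratio,
* trans effects ``t`` — strain-mean differences that appear in the parents
  but cancel in the F1 allelic ratio,
* optional condition-specific (TM-only) cis/trans effects, modelling
  regulatory variation only detectable under ER stress.

Parental counts are negative binomial around strain x condition means; F1
allelic counts are binomial (optionally beta-binomial) around the
cis-determined maternal proportion, decomposed over SNPs and replicates.
A configurable fraction of SNPs carries injected artifacts (quality flags,
sub-threshold coverage) to exercise the filtering rules.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd

from .io import (
    FLAG_VOCABULARY,
    GeneCountMatrix,
    _comment_header,
    write_counts,
    write_snp_table,
)

__all__ = [
    "ConfigError",
    "SimConfig",
    "SimTruth",
    "SimResult",
    "CATEGORIES",
    "expected_allelic_proportion",
    "true_category",
    "simulate_dataset",
    "write_truth",
    "read_truth",
    "write_dataset",
]

#: the seven regulatory divergence categories
CATEGORIES = (
    "cis",
    "trans",
    "cis_plus_trans",
    "cis_x_trans",
    "compensatory",
    "conserved",
    "ambiguous",
)

_FLAGS = tuple(sorted(FLAG_VOCABULARY))


class ConfigError(ValueError):
    """Invalid simulation configuration."""


def expected_allelic_proportion(c: float) -> float:
    """Maternal allelic proportion implied by a cis log2 effect ``c``.

    ``2**c / (2**c + 1)``; the analytic link between the generative cis
    effect and the binomial success probability of maternal reads.
    """
    if not np.isfinite(c):
        raise ValueError("cis effect must be finite")
    r = 2.0 ** float(c)
    return r / (r + 1.0)


def true_category(c: float, t: float) -> str:
    """Regulatory category implied by generative cis/trans effects."""
    if c == 0 and t == 0:
        return "conserved"
    if t == 0:
        return "cis"
    if c == 0:
        return "trans"
    parental = c + t
    if parental == 0:
        return "compensatory"
    return "cis_plus_trans" if np.sign(parental) == np.sign(c) else "cis_x_trans"


@dataclass
class SimConfig:
    """Generative parameters; the defaults define the study conditions.

    The design mirrors a 13-genotype x 2-treatment x 3-replicate
    experiment: eight parental strains and five F1 crosses that share the
    first (maternal, B6-analog) strain.  Effect fractions partition genes
    into disjoint regulatory classes; effect magnitudes are drawn uniformly
    on a log2 range with random sign.
    """

    n_genes: int = 2000
    strains: tuple = ("B6", "A", "129", "NOD", "NZO", "CAST", "PWK", "WSB")
    cross_fathers: tuple = ("129", "NOD", "NZO", "WSB", "CAST")
    n_replicates: int = 3
    library_size: float = 1.0e7
    library_size_cv: float = 0.1
    dispersion: float = 0.05
    baseline_log2_sd: float = 1.5
    snps_per_gene_mean: float = 3.0
    f1_library_size: float = 2.0e6
    f1_coverage: float | None = None
    frac_induced: float = 0.2
    induced_common_frac: float = 0.1
    induced_unique_frac: float = 0.4
    induction_log2_range: tuple = (0.7, 3.5)
    frac_induction_het: float = 0.3
    induction_strain_sd: float = 0.6
    frac_cis: float = 0.10
    frac_trans: float = 0.05
    frac_cis_and_trans: float = 0.02
    frac_compensatory: float = 0.02
    frac_cis_tm_only: float = 0.05
    frac_trans_tm_only: float = 0.02
    cis_effect_range: tuple = (0.5, 2.0)
    trans_effect_range: tuple = (0.5, 2.0)
    frac_shared_effect: float = 0.4
    artifact_snp_frac: float = 0.05
    low_coverage_record_frac: float = 0.03
    allelic_overdispersion: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ConfigError("n_genes must be >= 1")
        if self.n_replicates < 2:
            raise ConfigError("need at least 2 replicates")
        if len(self.strains) < 2:
            raise ConfigError("need at least 2 strains")
        if len(set(self.strains)) != len(self.strains):
            raise ConfigError("duplicate strain labels")
        unknown = set(self.cross_fathers) - set(self.strains[1:])
        if unknown:
            raise ConfigError(f"cross fathers not among paternal strains: {unknown}")
        fractions = {
            "frac_induced": self.frac_induced,
            "induced_common_frac": self.induced_common_frac,
            "induced_unique_frac": self.induced_unique_frac,
            "frac_induction_het": self.frac_induction_het,
            "frac_shared_effect": self.frac_shared_effect,
            "artifact_snp_frac": self.artifact_snp_frac,
            "low_coverage_record_frac": self.low_coverage_record_frac,
            "frac_cis": self.frac_cis,
            "frac_trans": self.frac_trans,
            "frac_cis_and_trans": self.frac_cis_and_trans,
            "frac_compensatory": self.frac_compensatory,
            "frac_cis_tm_only": self.frac_cis_tm_only,
            "frac_trans_tm_only": self.frac_trans_tm_only,
        }
        for name, value in fractions.items():
            if not 0.0 <= value <= 1.0:
                raise ConfigError(f"{name}={value} outside [0, 1]")
        class_total = (
            self.frac_cis
            + self.frac_trans
            + self.frac_cis_and_trans
            + self.frac_compensatory
            + self.frac_cis_tm_only
            + self.frac_trans_tm_only
        )
        if class_total > 1.0:
            raise ConfigError("regulatory class fractions sum above 1")
        if self.dispersion < 0:
            raise ConfigError("dispersion must be >= 0")
        if not 0.0 <= self.allelic_overdispersion < 1.0:
            raise ConfigError("allelic_overdispersion must be in [0, 1)")
        if min(self.library_size, self.f1_library_size) <= 0:
            raise ConfigError("library sizes must be positive")
        if self.f1_coverage is not None and self.f1_coverage <= 0:
            raise ConfigError("f1_coverage must be positive when set")
        for name in ("induction_log2_range", "cis_effect_range", "trans_effect_range"):
            lo, hi = getattr(self, name)
            if lo < 0 or hi < lo:
                raise ConfigError(f"{name} must satisfy 0 <= lo <= hi")

    @property
    def crosses(self) -> tuple:
        return tuple(f"x{f}" for f in self.cross_fathers)

    @property
    def maternal_strain(self) -> str:
        return self.strains[0]

    def to_dict(self) -> dict:
        d = asdict(self)
        for key, value in d.items():
            if isinstance(value, tuple):
                d[key] = list(value)
        return d

    @classmethod
    def from_dict(cls, data: Mapping) -> "SimConfig":
        kwargs = dict(data)
        for key in (
            "strains",
            "cross_fathers",
            "induction_log2_range",
            "cis_effect_range",
            "trans_effect_range",
        ):
            if key in kwargs and kwargs[key] is not None:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)


@dataclass
class SimTruth:
    """Generative ground truth.

    ``regulatory`` has one row per gene x cross x condition with the cis
    effect, trans effect and the implied category; ``induction`` one row
    per gene x strain with the TM log2 fold change; ``baseline`` maps gene
    to its relative abundance.
    """

    regulatory: pd.DataFrame
    induction: pd.DataFrame
    baseline: pd.Series

    def induced_genes(self, strain: str, min_log2fc: float) -> frozenset:
        sub = self.induction[self.induction["strain"] == strain]
        return frozenset(sub.loc[sub["log2fc"] >= min_log2fc, "gene"])


@dataclass
class SimResult:
    counts: GeneCountMatrix
    snps: pd.DataFrame
    truth: SimTruth
    config: SimConfig
    snp_samples: pd.DataFrame = field(default=None)


def _draw_effect(rng: np.random.Generator, effect_range: tuple) -> float:
    mag = rng.uniform(*effect_range)
    return mag if rng.random() < 0.5 else -mag


def _simulate_effects(config: SimConfig, rng: np.random.Generator):
    """Assign genes to regulatory classes and draw per-cross effects."""
    n, n_x = config.n_genes, len(config.cross_fathers)
    cis = np.zeros((n, n_x, 2))
    trans = np.zeros((n, n_x, 2))
    bounds = np.cumsum(
        [
            config.frac_cis,
            config.frac_trans,
            config.frac_cis_and_trans,
            config.frac_compensatory,
            config.frac_cis_tm_only,
            config.frac_trans_tm_only,
        ]
    )
    labels = ("cis", "trans", "cis_and_trans", "compensatory", "cis_tm_only", "trans_tm_only")
    u = rng.random(n)
    gene_class = np.array(["null"] * n, dtype=object)
    for label, hi, lo in zip(labels, bounds, np.concatenate([[0.0], bounds[:-1]])):
        gene_class[(u >= lo) & (u < hi)] = label

    def pick_crosses(shared_allowed: bool) -> np.ndarray:
        if shared_allowed and n_x >= 2 and rng.random() < config.frac_shared_effect:
            m = int(rng.integers(2, n_x + 1))
            return rng.choice(n_x, size=m, replace=False)
        return rng.choice(n_x, size=1)

    for g in range(n):
        label = gene_class[g]
        if label == "null":
            continue
        if label == "cis":
            e = _draw_effect(rng, config.cis_effect_range)
            cis[g, pick_crosses(True), :] = e
        elif label == "trans":
            e = _draw_effect(rng, config.trans_effect_range)
            trans[g, pick_crosses(True), :] = e
        elif label == "cis_and_trans":
            x = pick_crosses(False)
            cis[g, x, :] = _draw_effect(rng, config.cis_effect_range)
            trans[g, x, :] = _draw_effect(rng, config.trans_effect_range)
        elif label == "compensatory":
            x = pick_crosses(False)
            e = _draw_effect(rng, config.cis_effect_range)
            cis[g, x, :] = e
            trans[g, x, :] = -e
        elif label == "cis_tm_only":
            cis[g, pick_crosses(False), 1] = _draw_effect(rng, config.cis_effect_range)
        elif label == "trans_tm_only":
            trans[g, pick_crosses(False), 1] = _draw_effect(rng, config.trans_effect_range)
    return cis, trans, gene_class


def _simulate_induction(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Per-gene, per-strain TM induction log2 fold changes."""
    n, n_s = config.n_genes, len(config.strains)
    effects = np.zeros((n, n_s))
    induced = rng.random(n) < config.frac_induced
    for g in np.flatnonzero(induced):
        u = rng.random()
        if u < config.induced_common_frac:
            strains = np.arange(n_s)
        elif u < config.induced_common_frac + config.induced_unique_frac:
            strains = rng.choice(n_s, size=1)
        else:
            m = int(rng.integers(2, n_s)) if n_s > 2 else 1
            strains = rng.choice(n_s, size=m, replace=False)
        base = rng.uniform(*config.induction_log2_range)
        vals = np.full(strains.size, base)
        if rng.random() < config.frac_induction_het:
            vals = np.maximum(
                0.0, base + rng.normal(0.0, config.induction_strain_sd, strains.size)
            )
        effects[g, strains] = vals
    return effects


def _nb_sample(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    if dispersion <= 0:
        return rng.poisson(mu)
    size = 1.0 / dispersion
    p = size / (size + mu)
    return rng.negative_binomial(size, p)


def _allelic_draw(
    rng: np.random.Generator, coverage: np.ndarray, prop: np.ndarray, rho: float
) -> np.ndarray:
    if rho <= 0:
        return rng.binomial(coverage, prop)
    scale = (1.0 - rho) / rho
    p = rng.beta(np.maximum(prop * scale, 1e-9), np.maximum((1 - prop) * scale, 1e-9))
    return rng.binomial(coverage, p)


def simulate_dataset(config: SimConfig) -> SimResult:
    """Draw a complete synthetic dataset.

    Returns parental counts, the F1 per-SNP allele-count table (with sample
    metadata merged) and the ground-truth tables.  Fixing the seed fixes
    the output exactly.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    genes = np.array([f"gene{i:05d}" for i in range(n)])
    rel = 2.0 ** rng.normal(0.0, config.baseline_log2_sd, n)
    rel /= rel.sum()

    induction = _simulate_induction(config, rng)
    cis, trans, gene_class = _simulate_effects(config, rng)
    father_index = {f: i for i, f in enumerate(config.cross_fathers)}

    # ---- parental count matrix -------------------------------------------
    sample_ids, meta_rows, columns = [], [], []
    for s_idx, strain in enumerate(config.strains):
        for cond_idx, condition in enumerate(("control", "TM")):
            for rep in range(1, config.n_replicates + 1):
                expr = rel.copy()
                if condition == "TM":
                    expr = expr * 2.0 ** induction[:, s_idx]
                if strain in father_index:
                    x = father_index[strain]
                    expr = expr * 2.0 ** (-(cis[:, x, cond_idx] + trans[:, x, cond_idx]))
                depth = config.library_size * rng.uniform(
                    1 - config.library_size_cv, 1 + config.library_size_cv
                )
                mu = depth * expr / expr.sum()
                columns.append(_nb_sample(rng, mu, config.dispersion))
                sid = f"{strain}_{condition}_{rep}"
                sample_ids.append(sid)
                meta_rows.append((sid, strain, condition, rep))
    counts = pd.DataFrame(
        np.column_stack(columns).astype(np.int64), index=genes, columns=sample_ids
    )
    counts.index.name = "gene"
    samples = pd.DataFrame(
        meta_rows, columns=["sample", "strain", "condition", "replicate"]
    ).set_index("sample")
    matrix = GeneCountMatrix(counts=counts, samples=samples)

    # ---- F1 per-SNP allele counts ----------------------------------------
    frames = []
    snp_meta_rows = []
    n_reps = config.n_replicates
    for x, father in enumerate(config.cross_fathers):
        cross = f"x{father}"
        n_snps = 1 + rng.poisson(config.snps_per_gene_mean, n)
        total_snps = int(n_snps.sum())
        gene_of_snp = np.repeat(np.arange(n), n_snps)
        weights = rng.gamma(2.0, 1.0, total_snps)
        sums = np.zeros(n)
        np.add.at(sums, gene_of_snp, weights)
        weights = weights / sums[gene_of_snp]
        snp_rank = np.concatenate([np.arange(k) for k in n_snps])
        # SNP ids are cross-specific: each cross has its own discriminating
        # SNP set, and quality flags apply per cross
        snp_ids = np.array(
            [f"{cross}:{genes[g]}:snp{r + 1}" for g, r in zip(gene_of_snp, snp_rank)]
        )
        positions = rng.integers(1, 1_000_001, total_snps)
        is_artifact = rng.random(total_snps) < config.artifact_snp_frac
        flags = np.where(
            is_artifact, rng.choice(_FLAGS, size=total_snps), ""
        ).astype(object)
        artifact_prop = rng.beta(2.0, 2.0, total_snps)

        s_mat = 0  # maternal strain index
        s_pat = list(config.strains).index(father)
        for cond_idx, condition in enumerate(("control", "TM")):
            prop_gene = 2.0 ** cis[:, x, cond_idx]
            prop_gene = prop_gene / (prop_gene + 1.0)
            if config.f1_coverage is not None:
                gene_cov = np.full(n, float(config.f1_coverage))
            else:
                w = rel.copy()
                if condition == "TM":
                    w = w * 0.5 * (
                        2.0 ** induction[:, s_mat] + 2.0 ** induction[:, s_pat]
                    )
                gene_cov = n_reps * config.f1_library_size * w / w.sum()
            prop = np.where(
                is_artifact, artifact_prop, prop_gene[gene_of_snp]
            )
            mean_rec = gene_cov[gene_of_snp] * weights / n_reps
            for rep in range(1, n_reps + 1):
                sid = f"{cross}_{condition}_{rep}"
                coverage = rng.poisson(mean_rec)
                low = rng.random(total_snps) < config.low_coverage_record_frac
                coverage = np.where(low, rng.integers(0, 4, total_snps), coverage)
                maternal = _allelic_draw(
                    rng, coverage, prop, config.allelic_overdispersion
                )
                frames.append(
                    pd.DataFrame(
                        {
                            "gene": genes[gene_of_snp],
                            "snp_id": snp_ids,
                            "position": positions,
                            "sample": sid,
                            "maternal_count": maternal,
                            "paternal_count": coverage - maternal,
                            "flags": flags,
                            "cross": cross,
                            "condition": condition,
                            "replicate": rep,
                        }
                    )
                )
                snp_meta_rows.append((sid, cross, condition, rep))
    snps = pd.concat(frames, ignore_index=True)
    snp_samples = pd.DataFrame(
        snp_meta_rows, columns=["sample", "cross", "condition", "replicate"]
    ).set_index("sample")

    # ---- ground truth -----------------------------------------------------
    reg_rows = []
    for x, father in enumerate(config.cross_fathers):
        for cond_idx, condition in enumerate(("control", "TM")):
            for g in range(n):
                c = cis[g, x, cond_idx]
                t = trans[g, x, cond_idx]
                reg_rows.append(
                    (genes[g], f"x{father}", condition, c, t, true_category(c, t))
                )
    regulatory = pd.DataFrame(
        reg_rows, columns=["gene", "cross", "condition", "cis", "trans", "category"]
    )
    # net true TM log2 fold change per strain: the drawn induction effect
    # plus, for cross fathers, the expression shift contributed by
    # condition-specific regulatory effects (strain mean scales by
    # 2^-(c+t), so a TM-only effect changes the TM/control ratio)
    net = induction.copy()
    strain_list = list(config.strains)
    for x, father in enumerate(config.cross_fathers):
        s_idx = strain_list.index(father)
        net[:, s_idx] += (cis[:, x, 0] + trans[:, x, 0]) - (
            cis[:, x, 1] + trans[:, x, 1]
        )
    ind_rows = [
        (genes[g], strain, net[g, s], induction[g, s])
        for s, strain in enumerate(config.strains)
        for g in range(n)
    ]
    induction_df = pd.DataFrame(
        ind_rows, columns=["gene", "strain", "log2fc", "induction_effect"]
    )
    truth = SimTruth(
        regulatory=regulatory,
        induction=induction_df,
        baseline=pd.Series(rel, index=genes, name="relative_abundance"),
    )
    return SimResult(
        counts=matrix, snps=snps, truth=truth, config=config, snp_samples=snp_samples
    )


def write_truth(truth: SimTruth, path, induction_path=None) -> None:
    """Write the regulatory truth table (and optionally induction truth)."""
    with open(path, "w") as fh:
        fh.write(_comment_header({"table": "regulatory truth"}))
        truth.regulatory.to_csv(fh, sep="\t", index=False, float_format="%.6g")
    if induction_path is not None:
        with open(induction_path, "w") as fh:
            fh.write(_comment_header({"table": "induction truth"}))
            truth.induction.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def read_truth(path, induction_path=None) -> SimTruth:
    regulatory = pd.read_csv(path, sep="\t", comment="#")
    induction = (
        pd.read_csv(induction_path, sep="\t", comment="#")
        if induction_path is not None
        else pd.DataFrame(columns=["gene", "strain", "log2fc"])
    )
    return SimTruth(
        regulatory=regulatory,
        induction=induction,
        baseline=pd.Series(dtype=float),
    )


def write_dataset(result: SimResult, outdir) -> dict:
    """Write all simulated artifacts into ``outdir``; returns the paths."""
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": out / "counts.tsv",
        "samples": out / "samples.tsv",
        "snps": out / "snp_counts.tsv",
        "snp_samples": out / "snp_samples.tsv",
        "truth_regulatory": out / "truth_regulatory.tsv",
        "truth_induction": out / "truth_induction.tsv",
    }
    params = {"seed": result.config.seed, "n_genes": result.config.n_genes}
    write_counts(result.counts, paths["counts"], paths["samples"], params=params)
    write_snp_table(result.snps, paths["snps"], paths["snp_samples"], params=params)
    write_truth(result.truth, paths["truth_regulatory"], paths["truth_induction"])
    return paths
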