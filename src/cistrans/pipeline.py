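"""Stage orchestration behind the command-line interface.

Each stage reads its inputs from, and writes its outputs to, a single
run directory, so stages can be run individually or end-to-end.  All
tables are TSV with ``#`` provenance comments; the final report is JSON
with a versioned schema.  Conditions are always analyzed separately and
labeled ``control`` / ``TM``.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, ase, induction, regdiv, shared, simulate
from .io import (
    GeneCountMatrix,
    _comment_header,
    aggregate_gene_allele_counts,
    filter_snps,
    read_counts,
    read_snp_table,
)

__all__ = [
    "Thresholds",
    "RunConfig",
    "MissingArtifactError",
    "REPORT_SCHEMA_VERSION",
    "run_all",
    "stage_simulate",
    "stage_qc",
    "stage_induce",
    "stage_strain_effect",
    "stage_cistrans",
    "stage_ase",
    "stage_shared",
    "stage_report",
    "validate_report",
]

log = logging.getLogger("cistrans")

REPORT_SCHEMA_VERSION = 1


class MissingArtifactError(FileNotFoundError):
    """An upstream artifact is absent; names the subcommand that makes it."""

    def __init__(self, path: Path, producer: str):
        super().__init__(
            f"missing artifact {path.name!r}; run the {producer!r} subcommand first"
        )
        self.producer = producer


@dataclass
class Thresholds:
    """Significance and filtering thresholds used across stages."""

    induction_fold: float = induction.INDUCTION_FOLD
    induction_fdr: float = induction.INDUCTION_FDR
    strain_effect_fdr: float = 0.01
    cistrans_fdr: float = regdiv.CISTRANS_FDR
    ase_fdr: float = ase.ASE_FDR
    shared_fdr: float = shared.SHARED_FDR
    network_alpha: float = 0.05

    def validate(self) -> None:
        for name in (
            "induction_fdr",
            "strain_effect_fdr",
            "cistrans_fdr",
            "ase_fdr",
            "shared_fdr",
            "network_alpha",
        ):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name}={v} outside (0, 1]")
        if self.induction_fold < 1.0:
            raise ValueError("induction_fold must be >= 1")


@dataclass
class RunConfig:
    """Full run configuration: simulation parameters plus thresholds."""

    sim: simulate.SimConfig = field(default_factory=simulate.SimConfig)
    thresholds: Thresholds = field(default_factory=Thresholds)
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.seed is not None:
            self.sim.seed = int(self.seed)
        self.sim.validate()
        self.thresholds.validate()

    def to_yaml(self, path) -> None:
        payload = {
            "seed": self.sim.seed,
            "simulation": self.sim.to_dict(),
            "thresholds": vars(self.thresholds).copy(),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        sim = simulate.SimConfig.from_dict(payload.get("simulation", {}))
        thresholds = Thresholds(**payload.get("thresholds", {}))
        return cls(sim=sim, thresholds=thresholds, seed=payload.get("seed"))


def _require(path: Path, producer: str) -> Path:
    if not path.exists():
        raise MissingArtifactError(path, producer)
    return path


def _load_config(outdir: Path) -> RunConfig:
    return RunConfig.from_yaml(_require(outdir / "config.yaml", "simulate"))


def _write_tsv(frame: pd.DataFrame, path: Path, params: dict | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(_comment_header(params))
        frame.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def _write_json(payload: dict, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")


# --------------------------------------------------------------------------
# stages


def stage_simulate(config: RunConfig, outdir) -> dict:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log.info("simulating dataset (seed=%d)", config.sim.seed)
    result = simulate.simulate_dataset(config.sim)
    simulate.write_dataset(result, outdir)
    config.to_yaml(outdir / "config.yaml")
    return {
        "n_genes": config.sim.n_genes,
        "n_strains": len(config.sim.strains),
        "n_crosses": len(config.sim.crosses),
        "seed": config.sim.seed,
    }


def _load_panel(outdir: Path, qc: bool) -> GeneCountMatrix:
    matrix = read_counts(
        _require(outdir / "counts.tsv", "simulate"),
        _require(outdir / "samples.tsv", "simulate"),
    )
    if qc:
        meta = json.loads(_require(outdir / "qc.json", "qc").read_text())
        keep = meta["kept_samples"]
        matrix = matrix.subset_samples(keep)
        factors = pd.read_csv(
            _require(outdir / "tmm_factors.tsv", "qc"), sep="\t", comment="#"
        ).set_index("sample")["tmm_factor"]
        matrix.norm_factors = factors.loc[keep]
    return matrix


def stage_qc(outdir) -> dict:
    outdir = Path(outdir)
    matrix = _load_panel(outdir, qc=False)
    panel = induction.normalize_and_qc(matrix)
    factors = panel.matrix.norm_factors.rename("tmm_factor").reset_index()
    factors.columns = ["sample", "tmm_factor"]
    _write_tsv(factors, outdir / "tmm_factors.tsv")
    meta = {
        "removed": panel.removed,
        "kept_samples": list(panel.matrix.counts.columns),
        "common_dispersion": panel.dispersion,
    }
    _write_json(meta, outdir / "qc.json")
    return {
        "n_removed": sum(len(v) for v in panel.removed.values()),
        "common_dispersion": panel.dispersion,
    }


def stage_induce(outdir) -> dict:
    outdir = Path(outdir)
    config = _load_config(outdir)
    matrix = _load_panel(outdir, qc=True)
    meta = json.loads((outdir / "qc.json").read_text())
    dispersion = meta["common_dispersion"]
    th = config.thresholds
    results = {}
    for strain in config.sim.strains:
        log.info("induction test: %s", strain)
        res = induction.test_induction(
            matrix,
            strain,
            dispersion=dispersion,
            fold_threshold=th.induction_fold,
            fdr=th.induction_fdr,
        )
        _write_tsv(
            res,
            outdir / f"induction_{strain}.tsv",
            params={"fold": th.induction_fold, "fdr": th.induction_fdr},
        )
        results[strain] = res
    spectrum = induction.induced_gene_sets(results)
    _write_tsv(spectrum, outdir / "sharing_spectrum.tsv")
    return {
        "induced_per_strain": {
            s: int(r["induced"].sum()) for s, r in results.items()
        },
        "n_induced_union": int(len(spectrum)),
        "sharing": {
            label: int((spectrum["sharing"] == label).sum())
            for label in ("unique", "shared", "common")
        },
    }


def stage_strain_effect(outdir) -> dict:
    outdir = Path(outdir)
    config = _load_config(outdir)
    matrix = _load_panel(outdir, qc=True)
    th = config.thresholds
    fc = induction.fold_change_table(matrix)
    effects = induction.strain_effect(fc, fdr=th.strain_effect_fdr)
    _write_tsv(effects, outdir / "strain_effect.tsv", params={"fdr": th.strain_effect_fdr})
    top = (
        effects[effects["significant"]]
        .sort_values(["F", "gene"], ascending=[False, True])
        .head(30)["gene"]
        .tolist()
    )
    edges = induction.correlation_network(fc, top, alpha=th.network_alpha)
    _write_tsv(edges, outdir / "network_edges.tsv", params={"alpha": th.network_alpha})
    return {
        "n_strain_effect": int(effects["significant"].sum()),
        "n_network_nodes": len(top),
        "n_network_edges": int(len(edges)),
    }


def _load_gac(outdir: Path) -> pd.DataFrame:
    path = outdir / "gene_allele_counts.tsv"
    if path.exists():
        return pd.read_csv(path, sep="\t", comment="#")
    records = read_snp_table(
        _require(outdir / "snp_counts.tsv", "simulate"),
        _require(outdir / "snp_samples.tsv", "simulate"),
    )
    gac = aggregate_gene_allele_counts(filter_snps(records))
    _write_tsv(gac, path)
    return gac


def stage_cistrans(outdir) -> dict:
    outdir = Path(outdir)
    config = _load_config(outdir)
    matrix = _load_panel(outdir, qc=True)
    gac = _load_gac(outdir)
    th = config.thresholds
    maternal = config.sim.maternal_strain
    summary: dict = {}
    for father in config.sim.cross_fathers:
        cross = f"x{father}"
        calls_by_cond = {}
        for condition in ("control", "TM"):
            calls = regdiv.run_cistrans(
                matrix,
                gac,
                cross,
                father,
                condition,
                fdr=th.cistrans_fdr,
                maternal_strain=maternal,
            )
            _write_tsv(
                calls,
                outdir / f"cistrans_{cross}_{condition}.tsv",
                params={"fdr": th.cistrans_fdr},
            )
            calls_by_cond[condition] = calls
            summary.setdefault(cross, {})[condition] = regdiv.summarize_calls(calls)
        patterns = regdiv.compare_conditions(
            calls_by_cond["control"], calls_by_cond["TM"]
        )
        _write_tsv(patterns, outdir / f"condition_patterns_{cross}.tsv")
        summary[cross]["condition_patterns"] = {
            effect: {
                pattern: int(
                    (
                        (patterns["effect_type"] == effect)
                        & (patterns["pattern"] == pattern)
                    ).sum()
                )
                for pattern in ("both", "control-only", "TM-only")
            }
            for effect in ("cis", "trans")
        }
    _write_json(summary, outdir / "cistrans_summary.json")
    return summary


def stage_ase(outdir) -> dict:
    outdir = Path(outdir)
    config = _load_config(outdir)
    gac = _load_gac(outdir)
    th = config.thresholds
    maternal = config.sim.maternal_strain
    ind_path = outdir / f"induction_{maternal}.tsv"
    induced: frozenset | None = None
    if ind_path.exists():
        ind = pd.read_csv(ind_path, sep="\t", comment="#")
        induced = frozenset(ind.loc[ind["induced"], "gene"])
    results = {}
    for father in config.sim.cross_fathers:
        cross = f"x{father}"
        res = ase.test_ase_change(gac, cross, fdr=th.ase_fdr)
        _write_tsv(res, outdir / f"ase_{cross}.tsv", params={"fdr": th.ase_fdr})
        results[cross] = res
    induced_map = (
        {cross: induced for cross in results} if induced is not None else None
    )
    summary = ase.summarize_ase(results, induced_map)
    _write_tsv(summary, outdir / "ase_summary.tsv")
    return {
        row["cross"]: {
            "n_informative": int(row["n_informative"]),
            "ase_change_n": int(row["ase_change_n"]),
            "ase_change_pct": float(row["ase_change_pct"]),
        }
        for _, row in summary.iterrows()
    }


def stage_shared(outdir) -> dict:
    outdir = Path(outdir)
    config = _load_config(outdir)
    gac = _load_gac(outdir)
    th = config.thresholds
    shared_tables: dict[str, dict[str, pd.DataFrame]] = {}
    for condition in ("control", "TM"):
        calls_by_cross = {}
        for father in config.sim.cross_fathers:
            cross = f"x{father}"
            path = _require(
                outdir / f"cistrans_{cross}_{condition}.tsv", "cistrans"
            )
            calls_by_cross[cross] = pd.read_csv(path, sep="\t", comment="#")
        shared_tables[condition] = {}
        for effect in ("cis", "trans"):
            table = shared.find_shared(calls_by_cross, effect)
            table = shared.strain_effect_on_shared(
                table, gac, condition, fdr=th.shared_fdr
            )
            _write_tsv(
                table,
                outdir / f"shared_{effect}_{condition}.tsv",
                params={"fdr": th.shared_fdr},
            )
            shared_tables[condition][effect] = table
    summary = {}
    for effect in ("cis", "trans"):
        contrast = shared.condition_sharing_contrast(
            shared_tables["control"][effect], shared_tables["TM"][effect]
        )
        summary[effect] = contrast
        for cond in ("control", "TM"):
            tab = shared_tables[cond][effect]
            n_shared = int(tab["shared"].sum())
            summary[effect][cond]["strain_effect_n"] = int(
                tab["strain_effect"].sum()
            )
            summary[effect][cond]["strain_effect_pct"] = (
                100.0 * int(tab["strain_effect"].sum()) / n_shared
                if n_shared
                else None
            )
    _write_json(summary, outdir / "sharing_summary.json")
    return summary


def stage_report(outdir) -> dict:
    outdir = Path(outdir)
    config = _load_config(outdir)
    report = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "tool_version": __version__,
        "seed": config.sim.seed,
        "thresholds": vars(config.thresholds).copy(),
        "stages": {},
    }
    qc_path = _require(outdir / "qc.json", "qc")
    report["stages"]["qc"] = json.loads(qc_path.read_text())
    # induction
    induced = {}
    for strain in config.sim.strains:
        path = _require(outdir / f"induction_{strain}.tsv", "induce")
        res = pd.read_csv(path, sep="\t", comment="#")
        induced[strain] = int(res["induced"].sum())
    spectrum = pd.read_csv(
        _require(outdir / "sharing_spectrum.tsv", "induce"), sep="\t", comment="#"
    )
    report["stages"]["induction"] = {
        "induced_per_strain": induced,
        "n_induced_union": int(len(spectrum)),
        "sharing": {
            label: int((spectrum["sharing"] == label).sum())
            for label in ("unique", "shared", "common")
        },
    }
    effects = pd.read_csv(
        _require(outdir / "strain_effect.tsv", "strain-effect"), sep="\t", comment="#"
    )
    report["stages"]["strain_effect"] = {
        "n_significant": int(effects["significant"].sum())
    }
    report["stages"]["cistrans"] = json.loads(
        _require(outdir / "cistrans_summary.json", "cistrans").read_text()
    )
    ase_summary = pd.read_csv(
        _require(outdir / "ase_summary.tsv", "ase"), sep="\t", comment="#"
    )
    report["stages"]["ase"] = {
        row["cross"]: {
            "n_informative": int(row["n_informative"]),
            "ase_change_n": int(row["ase_change_n"]),
            "ase_change_pct": round(float(row["ase_change_pct"]), 4),
            "upregulated_n": int(row["upregulated_n"])
            if pd.notna(row["upregulated_n"])
            else None,
        }
        for _, row in ase_summary.iterrows()
    }
    report["stages"]["shared"] = json.loads(
        _require(outdir / "sharing_summary.json", "shared").read_text()
    )
    validate_report(report)
    _write_json(report, outdir / "report.json")
    return report


def validate_report(report: dict) -> None:
    """Check the run report against its (versioned) schema."""
    if report.get("schema_version") != REPORT_SCHEMA_VERSION:
        raise ValueError("unknown report schema version")
    required = {"seed", "thresholds", "stages"}
    missing = required - set(report)
    if missing:
        raise ValueError(f"report lacks keys: {sorted(missing)}")
    stage_keys = {"qc", "induction", "strain_effect", "cistrans", "ase", "shared"}
    missing = stage_keys - set(report["stages"])
    if missing:
        raise ValueError(f"report lacks stages: {sorted(missing)}")


def run_all(config: RunConfig, outdir) -> dict:
    """Run the full pipeline end-to-end; returns the final report."""
    outdir = Path(outdir)
    stage_simulate(config, outdir)
    stage_qc(outdir)
    stage_induce(outdir)
    stage_strain_effect(outdir)
    stage_cistrans(outdir)
    stage_ase(outdir)
    stage_shared(outdir)
    return stage_report(outdir)
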