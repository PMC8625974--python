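"""End-to-end orchestration: simulate/load -> DE -> targets -> network ->
hubs -> trends, with a machine-readable run report.

Every stage writes its intermediate tables under the output directory and
registers them in the report manifest; identical config + seed yields
byte-identical outputs (no timestamps, sorted keys, fixed float formats).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import __version__
from .analysis import count_triplets, hub_lncrnas
from .de import run_de
from .errors import ConfigError
from .io_core import (
    ExpressionMatrix,
    LocalizationTable,
    SampleDesign,
    read_expression_matrix,
    read_fasta,
    read_localization_table,
    read_sample_design,
    read_target_table,
    write_network,
    write_target_table,
)
from .network import (
    DEFAULT_PCC_POS,
    DEFAULT_RHO_NEG,
    DEFAULT_SPONGE_ALPHA,
    build_cerna_network,
    candidate_cerna_pairs,
    filter_mirna_cerna_pairs,
)
from .synthetic import SimConfig, SyntheticDataset, simulate_timecourse, write_dataset
from .targets import intersect_targets, predict_targets
from .trends import (
    DEFAULT_ALPHA,
    DEFAULT_MODEL_COUNT,
    DEFAULT_UNIT_CHANGE,
    assign_genes,
    classify_profiles,
    enumerate_candidate_profiles,
    profile_significance,
    select_model_profiles,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """One pipeline run: inputs (or a simulation), thresholds, seed, outputs."""

    out_dir: str = "cernakit_run"
    seed: int = 0
    # either simulate ...
    simulate: SimConfig | None = None
    # ... or load these inputs
    lnc_expr: str | None = None
    mirna_expr: str | None = None
    mrna_expr: str | None = None
    lnc_fasta: str | None = None
    mirna_fasta: str | None = None
    mrna_fasta: str | None = None
    localization: str | None = None
    design: str | None = None
    # optional external target tables intersected with the seed-match scan
    external_targets_lnc: list[str] = field(default_factory=list)
    external_targets_mrna: list[str] = field(default_factory=list)
    # thresholds (defaults are the published gates)
    fdr: float = 0.05
    lfc: float = 1.0
    pseudocount: float = 1.0
    rho: float = DEFAULT_RHO_NEG
    pcc: float = DEFAULT_PCC_POS
    alpha_sponge: float = DEFAULT_SPONGE_ALPHA
    top_k: int = 5
    stem_c: int = DEFAULT_UNIT_CHANGE
    stem_m: int = DEFAULT_MODEL_COUNT
    stem_alpha: float = DEFAULT_ALPHA
    keep_unlocalized: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = raw.pop("simulate", None)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        if sim is not None:
            if "stages" in sim:
                sim["stages"] = tuple(sim["stages"])
            if "base_abundance_range" in sim:
                sim["base_abundance_range"] = tuple(sim["base_abundance_range"])
            cfg.simulate = SimConfig(**sim)
        return cfg


def validate_config(config: RunConfig) -> list[str]:
    """Collect configuration problems; empty list means runnable."""
    issues: list[str] = []
    if not 0 < config.fdr <= 1:
        issues.append(f"fdr={config.fdr}: must be in (0, 1]")
    if config.lfc < 0:
        issues.append(f"lfc={config.lfc}: must be >= 0")
    if config.pseudocount <= 0:
        issues.append(f"pseudocount={config.pseudocount}: must be > 0")
    if not -1 <= config.rho < 0:
        issues.append(f"rho={config.rho}: anti-correlation gate must be in [-1, 0)")
    if not 0 <= config.pcc <= 1:
        issues.append(f"pcc={config.pcc}: must be in [0, 1]")
    if not 0 < config.alpha_sponge <= 1:
        issues.append(f"alpha_sponge={config.alpha_sponge}: must be in (0, 1]")
    if config.top_k < 1:
        issues.append(f"top_k={config.top_k}: must be >= 1")
    if config.stem_c < 1:
        issues.append(f"stem_c={config.stem_c}: must be >= 1")
    if config.stem_m < 1:
        issues.append(f"stem_m={config.stem_m}: must be >= 1")
    if not 0 < config.stem_alpha <= 1:
        issues.append(f"stem_alpha={config.stem_alpha}: must be in (0, 1]")
    if config.simulate is None:
        required = (
            "lnc_expr", "mirna_expr", "mrna_expr",
            "lnc_fasta", "mirna_fasta", "mrna_fasta",
        )
        for name in required:
            value = getattr(config, name)
            if value is None:
                issues.append(f"{name}: required when not simulating")
            elif not Path(value).exists():
                issues.append(f"{name}={value}: file does not exist")
        if config.localization is None and not config.keep_unlocalized:
            issues.append(
                "localization: required unless keep_unlocalized is set"
            )
        elif config.localization is not None and not Path(config.localization).exists():
            issues.append(f"localization={config.localization}: file does not exist")
    for name in ("external_targets_lnc", "external_targets_mrna"):
        for p in getattr(config, name):
            if not Path(p).exists():
                issues.append(f"{name}={p}: file does not exist")
    return issues


@dataclass
class RunReport:
    version: str
    seed: int
    config: dict[str, Any]
    funnel: dict[str, int]
    network_summary: dict[str, int]
    hubs: list[str]
    profiles: dict[str, Any]
    manifest: list[str]

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)


def _load_inputs(
    config: RunConfig, out: Path, manifest: list[str]
) -> tuple[ExpressionMatrix, ExpressionMatrix, ExpressionMatrix,
           dict, dict, dict, LocalizationTable, SampleDesign]:
    if config.simulate is not None:
        sim = dataclasses.replace(config.simulate, seed=config.seed)
        ds: SyntheticDataset = simulate_timecourse(sim)
        written = write_dataset(ds, out / "simulated")
        manifest.extend(str(p.relative_to(out)) for p in written)
        return (
            ds.lnc_expr, ds.mirna_expr, ds.mrna_expr,
            ds.lnc_fasta, ds.mirna_fasta, ds.mrna_fasta,
            ds.localization, ds.design,
        )
    lnc = read_expression_matrix(config.lnc_expr, "lncRNA")
    mirna = read_expression_matrix(config.mirna_expr, "miRNA")
    mrna = read_expression_matrix(config.mrna_expr, "mRNA")
    if config.design is not None:
        design = read_sample_design(config.design)
    else:
        design = SampleDesign.from_sample_ids(lnc.sample_ids)
    loc = (
        read_localization_table(config.localization)
        if config.localization is not None
        else LocalizationTable({})
    )
    return (
        lnc, mirna, mrna,
        read_fasta(config.lnc_fasta),
        read_fasta(config.mirna_fasta),
        read_fasta(config.mrna_fasta),
        loc, design,
    )


def run_pipeline(config: RunConfig) -> RunReport:
    issues = validate_config(config)
    if issues:
        raise ConfigError("invalid run config: " + "; ".join(issues))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: list[str] = []

    lnc, mirna, mrna, lnc_fa, mirna_fa, mrna_fa, loc, design = _load_inputs(
        config, out, manifest
    )
    funnel: dict[str, int] = {}

    # -- differential expression ------------------------------------------
    de_kwargs = dict(
        fdr_threshold=config.fdr,
        lfc_threshold=config.lfc,
        pseudocount=config.pseudocount,
    )
    pooled: dict[str, set[str]] = {}
    for expr in (lnc, mirna, mrna):
        per_comp, de_set = run_de(expr, design, **de_kwargs)
        pooled[expr.gene_class] = de_set
        rows = [
            dataclasses.asdict(r) for results in per_comp.values() for r in results
        ]
        name = f"de_{expr.gene_class.lower()}.tsv"
        pd.DataFrame(rows).to_csv(out / name, sep="\t", index=False,
                                  float_format="%.6g")
        manifest.append(name)
        funnel[f"de_{expr.gene_class}"] = len(de_set)

    de_lnc = lnc.subset(pooled["lncRNA"]) if pooled["lncRNA"] else None
    de_mirna = mirna.subset(pooled["miRNA"]) if pooled["miRNA"] else None
    de_mrna = mrna.subset(pooled["mRNA"]) if pooled["mRNA"] else None
    if de_lnc is None or de_mirna is None or de_mrna is None:
        raise ConfigError("a gene class has no DE genes; nothing to build on")

    # -- target prediction -------------------------------------------------
    de_mirna_fa = {k: v for k, v in mirna_fa.items() if k in pooled["miRNA"]}
    de_lnc_fa = {k: v for k, v in lnc_fa.items() if k in pooled["lncRNA"]}
    de_mrna_fa = {k: v for k, v in mrna_fa.items() if k in pooled["mRNA"]}
    targets_lnc = predict_targets(de_mirna_fa, de_lnc_fa, "lncRNA")
    targets_mrna = predict_targets(de_mirna_fa, de_mrna_fa, "mRNA")
    if config.external_targets_lnc:
        tables = [targets_lnc] + [
            read_target_table(p) for p in config.external_targets_lnc
        ]
        targets_lnc = intersect_targets(tables)
    if config.external_targets_mrna:
        tables = [targets_mrna] + [
            read_target_table(p) for p in config.external_targets_mrna
        ]
        targets_mrna = intersect_targets(tables)
    write_target_table(targets_lnc, out / "targets_lnc.tsv")
    write_target_table(targets_mrna, out / "targets_mrna.tsv")
    manifest.extend(["targets_lnc.tsv", "targets_mrna.tsv"])
    funnel["target_pairs_lnc"] = len(targets_lnc)
    funnel["target_pairs_mrna"] = len(targets_mrna)

    # -- correlation gate --------------------------------------------------
    lnc_pairs = filter_mirna_cerna_pairs(targets_lnc, de_mirna, de_lnc, config.rho)
    mrna_pairs = filter_mirna_cerna_pairs(targets_mrna, de_mirna, de_mrna, config.rho)
    funnel["correlation_gated_lnc"] = len(lnc_pairs)
    funnel["correlation_gated_mrna"] = len(mrna_pairs)

    # -- candidate pairs, sponge test, localization ------------------------
    candidates = candidate_cerna_pairs(lnc_pairs, mrna_pairs)
    build = build_cerna_network(
        candidates, de_lnc, de_mrna, loc,
        threshold_pos=config.pcc,
        alpha=config.alpha_sponge,
        keep_unlocalized=config.keep_unlocalized,
    )
    funnel.update(build.funnel)
    pair_rows = [
        {
            "lnc_id": p.lnc_id,
            "mrna_id": p.mrna_id,
            "shared_mirnas": ",".join(sorted(p.shared_mirnas)),
            "k": p.k, "K": p.K, "n": p.n, "N": p.N,
            "pcc": p.pcc, "p_sponge": p.p_sponge,
        }
        for p in build.retained_pairs
    ]
    pd.DataFrame(
        pair_rows,
        columns=["lnc_id", "mrna_id", "shared_mirnas", "k", "K", "n", "N",
                 "pcc", "p_sponge"],
    ).to_csv(out / "cerna_pairs.tsv", sep="\t", index=False, float_format="%.6g")
    pd.DataFrame(
        [(t.lncrna, t.mirna, t.mrna) for t in build.triplets],
        columns=["lnc_id", "mirna_id", "mrna_id"],
    ).to_csv(out / "cerna_triplets.tsv", sep="\t", index=False)
    manifest.extend(["cerna_pairs.tsv", "cerna_triplets.tsv"])

    network_summary = count_triplets(build.triplets)
    hubs: list[str] = []
    if build.network.n_nodes > 0:
        write_network(build.network, out / "cerna_network.gml", "gml")
        manifest.append("cerna_network.gml")
        hubs = hub_lncrnas(build.network, config.top_k)

    # -- trend clustering over network mRNAs -------------------------------
    profiles_report: dict[str, Any] = {"significant": {}, "categories": {}}
    network_mrnas = {t.mrna for t in build.triplets}
    T = len(design.stage_order)
    profiles = select_model_profiles(
        enumerate_candidate_profiles(T, config.stem_c), config.stem_m
    )
    if network_mrnas:
        trend_expr = de_mrna.subset(network_mrnas)
        assignment = assign_genes(trend_expr, design, profiles)
        assignment = profile_significance(
            assignment, trend_expr, design, profiles, config.stem_alpha
        )
        labels = classify_profiles(profiles)
        assign_rows = [
            {"gene_id": g, "profile_id": pid, "distance": d}
            for g, (pid, d) in sorted(assignment.assignments.items())
        ]
        pd.DataFrame(
            assign_rows, columns=["gene_id", "profile_id", "distance"]
        ).to_csv(out / "trend_assignments.tsv", sep="\t", index=False,
                 float_format="%.6g")
        prof_rows = [
            {
                "profile_id": p.profile_id,
                "values": ",".join(map(str, p.values)),
                "observed": assignment.observed[p.profile_id],
                "expected": assignment.expected[p.profile_id],
                "p_value": assignment.p_values[p.profile_id],
                "significant": assignment.significant[p.profile_id],
                "category": labels[p.profile_id],
            }
            for p in profiles
        ]
        pd.DataFrame(prof_rows).to_csv(
            out / "trend_profiles.tsv", sep="\t", index=False, float_format="%.6g"
        )
        manifest.extend(["trend_assignments.tsv", "trend_profiles.tsv"])
        profiles_report["significant"] = {
            str(pid): assignment.p_values[pid]
            for pid, sig in sorted(assignment.significant.items())
            if sig
        }
        profiles_report["categories"] = {
            str(pid): labels[pid]
            for pid, sig in sorted(assignment.significant.items())
            if sig
        }

    config_echo = dataclasses.asdict(config)
    report = RunReport(
        version=__version__,
        seed=config.seed,
        config=config_echo,
        funnel=funnel,
        network_summary=network_summary,
        hubs=hubs,
        profiles=profiles_report,
        manifest=sorted(manifest + ["run_report.json"]),
    )
    (out / "run_report.json").write_text(
        json.dumps(report.to_dict(), indent=2, sort_keys=True, default=str) + "\n"
    )
    return report
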