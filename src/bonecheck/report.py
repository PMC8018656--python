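"""Pipeline orchestration and the compliance report.

Stages run in a hard order — species gating precedes matching, so a
non-lion farm sample is excluded from the lion match pool and reported
as an interception; then duplicates, farm-to-port matching, the weight
audit and finally the anomaly ledger. Errors (e.g. a weight-manifest
tag with no genotype) are accumulated and reported rather than fatal:
compliance work needs a complete picture of partial data.

The JSON rendering is deterministic: re-running with the same config,
inputs and seed yields a byte-identical report.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from . import genodata, markerqc, match as matchmod, species as speciesmod, weights as weightsmod
from .genodata import SampleRecord, Site, SnpCallSet, StrGenotype, WeightRecord
from .species import FinalCall, SpeciesAssignment, SpeciesThresholds
from .match import AnomalyLedger, MatchClass, MatchParams, MatchResult
from .synth import Sample

SCHEMA_ID = "bonecheck-report/1"

__all__ = [
    "RunConfig",
    "PipelineInputs",
    "ComplianceReport",
    "run_pipeline",
    "run_pipeline_data",
    "render_report",
]


@dataclass
class RunConfig:
    match_params: MatchParams = field(default_factory=MatchParams)
    species_thresholds: SpeciesThresholds = field(default_factory=SpeciesThresholds)
    weight_threshold_kg: float = 0.6
    default_packaging_kg: float = 0.0
    mismatch_tolerance: int = 0
    seed: int = 0

    def digest(self) -> str:
        payload = json.dumps(
            {
                "alpha": self.match_params.alpha,
                "k_max": self.match_params.k_max,
                "r_identity_floor": self.match_params.r_identity_floor,
                "q_lion_min": self.species_thresholds.q_lion_min,
                "q_tiger_max": self.species_thresholds.q_tiger_max,
                "weight_threshold_kg": self.weight_threshold_kg,
                "default_packaging_kg": self.default_packaging_kg,
                "mismatch_tolerance": self.mismatch_tolerance,
                "seed": self.seed,
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class PipelineInputs:
    farm_genotypes: Path
    port_genotypes: Path
    snp_calls: Path
    weights: Path
    lion_panel: Path
    tiger_panel: Path

    def paths(self) -> list[Path]:
        return [
            self.farm_genotypes,
            self.port_genotypes,
            self.snp_calls,
            self.weights,
            self.lion_panel,
            self.tiger_panel,
        ]


@dataclass
class ComplianceReport:
    schema: str
    metadata: dict
    species_summary: dict
    ledger: AnomalyLedger
    weight_summary: dict
    detail: list[dict]
    errors: list[str]
    marker_summary: dict = field(default_factory=dict)

    @property
    def has_anomalies(self) -> bool:
        return any(c["n_anomalies"] > 0 for c in self.ledger.counts.values())

    def to_dict(self) -> dict:
        return {
            "schema": self.schema,
            "metadata": self.metadata,
            "species_summary": self.species_summary,
            "anomaly_ledger": {
                "entries": [e.__dict__ for e in self.ledger.entries],
                "duplicates": [d.__dict__ for d in self.ledger.duplicates],
                "counts": self.ledger.counts,
            },
            "weight_summary": self.weight_summary,
            "marker_summary": self.marker_summary,
            "detail": self.detail,
            "errors": self.errors,
        }


def _load_samples(
    genotype_path: Path, snp_by_sample: Mapping[str, SnpCallSet]
) -> list[Sample]:
    records, genotypes = genodata.read_genotype_table(genotype_path)
    out = []
    default_loci = ("CR", "12S", "16S")
    for rec, geno in zip(records, genotypes):
        snp = snp_by_sample.get(
            rec.sample_id,
            SnpCallSet({l: genodata.SnpAllele.UNDETERMINED for l in default_loci}),
        )
        out.append(Sample(rec, geno, snp))
    return out


def run_pipeline(config: RunConfig, inputs: PipelineInputs) -> ComplianceReport:
    """File-based pipeline entry point."""
    snp_meta, snp_calls = genodata.read_snp_table(inputs.snp_calls)
    snp_by_sample = {m["sample_id"]: c for m, c in zip(snp_meta, snp_calls)}
    farm = _load_samples(inputs.farm_genotypes, snp_by_sample)
    port = _load_samples(inputs.port_genotypes, snp_by_sample)
    weight_records = genodata.read_weight_table(inputs.weights)
    _, lion_panel = genodata.read_genotype_table(inputs.lion_panel)
    _, tiger_panel = genodata.read_genotype_table(inputs.tiger_panel)
    checksums = {
        name: info["sha256"]
        for name, info in genodata.custody_digest(inputs.paths())["files"].items()
    }
    return run_pipeline_data(
        farm, port, weight_records, lion_panel, tiger_panel, config, checksums
    )


def run_pipeline_data(
    farm_samples: Sequence[Sample],
    port_samples: Sequence[Sample],
    weight_records: Sequence[WeightRecord],
    lion_panel: Sequence[StrGenotype],
    tiger_panel: Sequence[StrGenotype],
    config: RunConfig = RunConfig(),
    input_checksums: Mapping[str, str] | None = None,
) -> ComplianceReport:
    """In-memory pipeline: species -> duplicates -> matching -> weights -> ledger."""
    errors: list[str] = []

    # --- stage 1: species assignment (gating) ------------------------------
    assignments: list[SpeciesAssignment] = []
    for sample in list(farm_samples) + list(port_samples):
        try:
            sa = speciesmod.assign_sample(
                sample.record.sample_id,
                sample.snp,
                genotype=sample.genotype,
                lion_panel=lion_panel,
                tiger_panel=tiger_panel,
                thresholds=config.species_thresholds,
            )
        except ValueError as exc:
            errors.append(f"species assignment failed for {sample.record.sample_id}: {exc}")
            sa = SpeciesAssignment(
                sample.record.sample_id, speciesmod.SpeciesCall.INCONCLUSIVE
            )
        assignments.append(sa)
    call_by_id = {sa.sample_id: sa for sa in assignments}
    lion_farm = [
        s
        for s in farm_samples
        if call_by_id[s.record.sample_id].final_call is FinalCall.LION
    ]
    non_lion_port_ids = {
        s.record.sample_id
        for s in port_samples
        if call_by_id[s.record.sample_id].final_call is not FinalCall.LION
    }

    # --- stage 2: duplicates ----------------------------------------------
    reference_freqs = matchmod.cohort_frequencies([s.genotype for s in lion_farm])
    duplicates = matchmod.find_duplicates(
        lion_farm, config.mismatch_tolerance, reference_freqs
    )

    # --- stage 3: farm-to-port matching ------------------------------------
    results: list[MatchResult] = []
    rmat = None
    lion_port = [s for s in port_samples if s.record.sample_id not in non_lion_port_ids]
    if lion_port and len(lion_farm) >= 10:
        results, rmat = matchmod.match_cohort(
            port_samples,
            lion_farm,
            reference_freqs,
            config.match_params,
            exclude_port_ids=non_lion_port_ids,
            errors=errors,
        )
    elif port_samples:
        errors.append("matching skipped: fewer than 10 lion farm samples")

    # --- stage 4: weight audit ---------------------------------------------
    weight_summary: dict = {}
    flagged_weight_tags: set[str] = set()
    genotype_tags = {s.record.tag for s in farm_samples}
    for rec in weight_records:
        if rec.tag not in genotype_tags:
            errors.append(f"weight manifest tag {rec.tag!r} absent from genotype table")
    try:
        audit = weightsmod.audit_pairs(
            weight_records,
            threshold_kg=config.weight_threshold_kg,
            default_packaging_kg=config.default_packaging_kg,
        )
        flagged_weight_tags = set(audit.flagged_tags)
        weight_summary = {
            "n_pairs": audit.n_pairs,
            "n_flagged": audit.n_flagged,
            "flagged_tags": sorted(flagged_weight_tags),
            "paired_t": audit.paired_t,
            "paired_t_p": audit.paired_t_p,
            "trader_anova_F": audit.trader_anova_F,
            "trader_anova_p": audit.trader_anova_p,
            "site_means": audit.site_means,
            "threshold_kg": audit.threshold_kg,
        }
    except ValueError as exc:
        errors.append(f"weight audit skipped: {exc}")

    # --- stage 5: anomaly ledger --------------------------------------------
    ledger = matchmod.classify_anomalies(
        results,
        duplicates,
        assignments,
        [s.record for s in farm_samples],
        [s.record for s in port_samples],
    )

    # --- assemble ------------------------------------------------------------
    species_counts: dict[str, dict[str, int]] = {}
    for sample in list(farm_samples) + list(port_samples):
        sa = call_by_id[sample.record.sample_id]
        site = sample.record.site.value
        species_counts.setdefault(site, {})
        species_counts[site][sa.final_call.value] = (
            species_counts[site].get(sa.final_call.value, 0) + 1
        )

    result_by_id = {m.port_sample_id: m for m in results}
    anomaly_by_tag_site: dict[tuple[str, str], list[str]] = {}
    for e in ledger.entries:
        anomaly_by_tag_site.setdefault((e.tag, e.site), []).append(e.anomaly)
    detail = []
    for sample in list(farm_samples) + list(port_samples):
        rec = sample.record
        sa = call_by_id[rec.sample_id]
        m = result_by_id.get(rec.sample_id)
        detail.append(
            {
                "sample_id": rec.sample_id,
                "tag": rec.tag,
                "site": rec.site.value,
                "year": rec.year,
                "facility": rec.facility_id,
                "species_call": sa.final_call.value,
                "match_class": m.match_class.value if m else None,
                "matched_farm_sample": m.matched_farm_sample if m else None,
                "r_same_tag": None if m is None or np.isnan(m.r_same_tag) else round(m.r_same_tag, 6),
                "anomalies": sorted(anomaly_by_tag_site.get((rec.tag, rec.site.value), [])),
                "weight_flag": rec.tag in flagged_weight_tags and rec.site is Site.PORT,
            }
        )

    n_match = sum(1 for m in results if m.match_class is MatchClass.MATCH)
    n_scored = sum(
        1 for m in results if m.match_class is not MatchClass.NON_TARGET_SPECIES
    )
    metadata = {
        "seed": config.seed,
        "config_digest": config.digest(),
        "input_checksums": dict(input_checksums or {}),
        "n_farm_samples": len(farm_samples),
        "n_port_samples": len(port_samples),
        "n_port_matched": n_match,
        "port_match_rate": (n_match / n_scored) if n_scored else None,
    }
    return ComplianceReport(
        schema=SCHEMA_ID,
        metadata=metadata,
        species_summary=species_counts,
        ledger=ledger,
        weight_summary=weight_summary,
        detail=detail,
        errors=errors,
    )


def render_report(report: ComplianceReport, fmt: str = "json") -> str:
    """Render as machine-readable JSON (lossless round-trip, deterministic
    bytes) or a human-readable Markdown summary."""
    if fmt == "json":
        return json.dumps(report.to_dict(), indent=2, sort_keys=True) + "\n"
    if fmt in ("markdown", "text"):
        lines = ["# Compliance report", ""]
        md = report.metadata
        lines.append(f"- farm samples: {md['n_farm_samples']}")
        lines.append(f"- port samples: {md['n_port_samples']}")
        if md.get("port_match_rate") is not None:
            lines.append(
                f"- port tag matches: {md['n_port_matched']} "
                f"({100.0 * md['port_match_rate']:.1f}%)"
            )
        lines.append("")
        lines.append("## Anomalies")
        for key, c in sorted(report.ledger.counts.items()):
            lines.append(
                f"- {key}: {c['n_anomalies']}/{c['n_total']} "
                f"({100.0 * c['proportion']:.1f}%)"
            )
        for e in report.ledger.entries:
            lines.append(
                f"  - {e.site}/{e.year} tag {e.tag}: {e.anomaly} ({e.interpretation})"
            )
        if report.weight_summary:
            ws = report.weight_summary
            lines.append("")
            lines.append("## Weight audit")
            lines.append(
                f"- {ws['n_flagged']}/{ws['n_pairs']} pairs exceed "
                f"+{ws['threshold_kg']} kg"
            )
        if report.errors:
            lines.append("")
            lines.append("## Errors")
            for err in report.errors:
                lines.append(f"- {err}")
        return "\n".join(lines) + "\n"
    raise ValueError(f"unknown report format {fmt!r}")
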