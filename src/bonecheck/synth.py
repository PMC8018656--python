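"""Synthetic cohorts for exercising the compliance pipeline end to end.

The generator emulates an annual captive-lion skeleton export quota: a
farm cohort of tagged skeletons genotyped at an STR panel, a port
spot-check subset (a fixed fraction of every consignment, at least one
per batch), mtDNA SNP species calls, farm/port weight manifests, and a
machine-readable ground-truth table. Anomalies observed in real audits
are planted on demand:

* ``non_target_species`` — a tiger skeleton submitted under the lion quota;
* ``reassigned_tag``     — a port sample carrying tag *t* but the genotype
  of a different individual from the same facility (mislabelling /
  tag-swapping);
* ``pooled_no_match``    — a port genotype from an individual never
  sampled at any farm (skeleton pooling);
* ``duplicate_individual`` — two farm tags sharing one genotype.

Defaults mirror the 2018 study conditions: an 800-skeleton quota, a
12.5% spot-check, 18 STR loci with 5–11 alleles each, three diagnostic
mtDNA SNP loci, 20-individual reference panels per species, farm
weights 16.6 ± 5.5 kg, a 0.88 farm-to-port desiccation factor and
1.1 kg mean packaging.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .genodata import (
    SampleRecord,
    Site,
    SnpAllele,
    SnpCallSet,
    SpeciesLabel,
    StrGenotype,
    WeightRecord,
)

__all__ = [
    "SpeciesPanel",
    "SnpLocusDef",
    "AnomalyCounts",
    "GenotypingError",
    "CohortConfig",
    "WeightParams",
    "Sample",
    "TruthTable",
    "make_species_panels",
    "sample_genotype",
    "sample_reference_panel",
    "simulate_cohort",
    "assign_consignments",
    "simulate_weights",
]

SNP_LOCI = ("CR", "12S", "16S")


@dataclass
class SpeciesPanel:
    """Per-locus allele frequencies parameterizing one species."""

    species_label: SpeciesLabel
    loci: list[str]
    freqs: dict[str, dict[int, float]]

    def __post_init__(self) -> None:
        for locus in self.loci:
            table = self.freqs[locus]
            if not table:
                raise ValueError(f"locus {locus} has no alleles")
            if any(a <= 0 or int(a) != a for a in table):
                raise ValueError(f"allele sizes must be positive integers at {locus}")
            s = sum(table.values())
            if abs(s - 1.0) > 1e-9:
                raise ValueError(f"frequencies at {locus} sum to {s}, not 1")

    def alleles(self, locus: str) -> list[int]:
        return [a for a, f in self.freqs[locus].items() if f > 0]

    def mean_allele_count(self) -> float:
        return float(np.mean([len(self.alleles(l)) for l in self.loci]))


@dataclass(frozen=True)
class SnpLocusDef:
    """A fixed-difference mitochondrial SNP separating the two species."""

    name: str
    lion_base: str
    tiger_base: str


@dataclass
class AnomalyCounts:
    non_target_species: int = 0
    reassigned_tag: int = 0
    pooled_no_match: int = 0
    duplicate_individual: int = 0  # number of tag *pairs* sharing one genotype


@dataclass
class GenotypingError:
    dropout: float = 0.0       # per-allele probability of a missing call
    false_allele: float = 0.0  # per-locus probability of a random allele swap


@dataclass
class CohortConfig:
    quota_size: int = 800
    spot_fraction: float = 0.125
    n_str_loci: int = 18
    allele_count_range: tuple[int, int] = (5, 11)
    n_snp_loci: int = 3
    divergence: float = 0.8
    panel_size: int = 20  # reference individuals per species
    anomalies: AnomalyCounts = field(default_factory=AnomalyCounts)
    genotyping_error: GenotypingError = field(default_factory=GenotypingError)
    seed: int = 0
    year: int = 2018
    n_facilities: int = 7
    consignment_size: int = 50

    def __post_init__(self) -> None:
        if not (0.0 < self.spot_fraction <= 1.0):
            raise ValueError("spot_fraction must be in (0, 1]")
        a = self.anomalies
        planted = (
            a.non_target_species
            + a.reassigned_tag
            + a.pooled_no_match
            + 2 * a.duplicate_individual
        )
        if planted > self.quota_size:
            raise ValueError("anomaly counts exceed available tags")

    @classmethod
    def scenario_2018(cls, seed: int = 0) -> "CohortConfig":
        """The 2018-quota audit scenario: 800 skeletons, 12.5% spot-check,
        one tiger, one reassigned tag, four pooled port samples and one
        duplicate farm pair."""
        return cls(
            anomalies=AnomalyCounts(
                non_target_species=1,
                reassigned_tag=1,
                pooled_no_match=4,
                duplicate_individual=1,
            ),
            seed=seed,
        )

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["allele_count_range"] = list(self.allele_count_range)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True), encoding="utf-8")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortConfig":
        d = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        d["allele_count_range"] = tuple(d["allele_count_range"])
        d["anomalies"] = AnomalyCounts(**d.get("anomalies", {}))
        d["genotyping_error"] = GenotypingError(**d.get("genotyping_error", {}))
        return cls(**d)


@dataclass
class WeightParams:
    farm_mean: float = 16.6
    farm_sd: float = 5.5
    floor_kg: float = 5.0  # paper-range floor; observed skeletons run 6.0-38.0 kg
    desiccation_mean: float = 0.88  # farm->port cleaning/drying weight retention
    desiccation_sd: float = 0.03
    packaging_mean: float = 1.1
    packaging_sd: float = 0.1

    def __post_init__(self) -> None:
        if self.farm_mean <= 0 or self.farm_sd <= 0:
            raise ValueError("farm weight mean and SD must be positive")


@dataclass
class Sample:
    record: SampleRecord
    genotype: StrGenotype
    snp: SnpCallSet


@dataclass
class FarmTruth:
    individual_id: str
    species: SpeciesLabel
    anomaly_class: str  # NONE | NON_TARGET_SPECIES | DUPLICATE_INDIVIDUAL


@dataclass
class PortTruth:
    true_individual_id: str
    anomaly_class: str  # NONE | REASSIGNED_TAG | POOLED_NO_MATCH
    externally_sourced: bool = False


@dataclass
class TruthTable:
    farm: dict[str, FarmTruth]
    port: dict[str, PortTruth]

    def class_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for t in self.farm.values():
            if t.anomaly_class != "NONE":
                out[t.anomaly_class] = out.get(t.anomaly_class, 0) + 1
        for t in self.port.values():
            if t.anomaly_class != "NONE":
                out[t.anomaly_class] = out.get(t.anomaly_class, 0) + 1
        return out

    def to_frame(self):
        import pandas as pd

        rows = []
        for tag, t in self.farm.items():
            rows.append(
                {
                    "tag": tag,
                    "site": "FARM",
                    "individual_id": t.individual_id,
                    "species": t.species.value,
                    "anomaly_class": t.anomaly_class,
                }
            )
        for tag, t in self.port.items():
            rows.append(
                {
                    "tag": tag,
                    "site": "PORT",
                    "individual_id": t.true_individual_id,
                    "species": "",
                    "anomaly_class": t.anomaly_class,
                }
            )
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Panels
# ---------------------------------------------------------------------------

def make_species_panels(
    n_loci: int = 18,
    allele_count_range: tuple[int, int] = (5, 11),
    divergence: float = 0.8,
    seed: int = 0,
) -> tuple[SpeciesPanel, SpeciesPanel, list[SnpLocusDef]]:
    """Build lion and tiger allele-frequency panels plus diagnostic SNPs.

    Per locus the allele count is uniform on `allele_count_range`; a base
    frequency vector is drawn Dirichlet(1,...,1); `divergence` controls the
    fraction of alleles made private to each species by masking them to zero
    frequency in the other species (split evenly, disjoint sets), after
    which frequencies are renormalized. divergence=0 leaves the two tables
    identical.
    """
    if n_loci < 1:
        raise ValueError("n_loci must be >= 1")
    lo, hi = allele_count_range
    if lo > hi or lo < 2 or hi > 30:
        raise ValueError("allele_count_range must be a non-empty range within [2, 30]")
    if not (0.0 <= divergence <= 1.0):
        raise ValueError("divergence must be in [0, 1]")
    rng = np.random.default_rng(seed)
    loci = [f"L{i + 1:02d}" for i in range(n_loci)]
    lion_freqs: dict[str, dict[int, float]] = {}
    tiger_freqs: dict[str, dict[int, float]] = {}
    for locus in loci:
        k = int(rng.integers(lo, hi + 1))
        base_size = int(rng.integers(40, 120))
        sizes = [2 * base_size + 2 * i for i in range(k)]  # dinucleotide ladder
        base = rng.dirichlet(np.ones(k))
        n_priv = int(math.floor(divergence * k / 2.0))
        n_priv = min(n_priv, (k - 1) // 2)  # keep >=1 allele per species
        perm = rng.permutation(k)
        lion_private = set(perm[:n_priv])
        tiger_private = set(perm[n_priv: 2 * n_priv])
        lion_p = base.copy()
        tiger_p = base.copy()
        for i in tiger_private:
            lion_p[i] = 0.0
        for i in lion_private:
            tiger_p[i] = 0.0
        lion_p /= lion_p.sum()
        tiger_p /= tiger_p.sum()
        lion_freqs[locus] = {s: float(f) for s, f in zip(sizes, lion_p)}
        tiger_freqs[locus] = {s: float(f) for s, f in zip(sizes, tiger_p)}
    bases = "ACGT"
    snp_defs = []
    for name in SNP_LOCI:
        i, j = rng.choice(4, size=2, replace=False)
        snp_defs.append(SnpLocusDef(name, bases[i], bases[j]))
    lion = SpeciesPanel(SpeciesLabel.LION, loci, lion_freqs)
    tiger = SpeciesPanel(SpeciesLabel.TIGER, loci, tiger_freqs)
    return lion, tiger, snp_defs


def sample_genotype(panel: SpeciesPanel, rng: np.random.Generator) -> StrGenotype:
    """Draw one diploid multilocus genotype under Hardy–Weinberg."""
    alleles = {}
    for locus in panel.loci:
        table = panel.freqs[locus]
        sizes = np.array(list(table.keys()))
        p = np.array(list(table.values()))
        pair = rng.choice(sizes, size=2, p=p)
        alleles[locus] = (int(pair[0]), int(pair[1]))
    return StrGenotype(alleles)


def sample_reference_panel(
    panel: SpeciesPanel, n: int, rng: np.random.Generator
) -> list[StrGenotype]:
    return [sample_genotype(panel, rng) for _ in range(n)]


def _snp_calls(species: SpeciesLabel) -> SnpCallSet:
    call = SnpAllele.LION if species is SpeciesLabel.LION else SnpAllele.TIGER
    return SnpCallSet({name: call for name in SNP_LOCI})


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------

def assign_consignments(
    records: Sequence[SampleRecord], consignment_size: int
) -> dict[str, str]:
    """Deterministic tag -> consignment_id map: consecutive chunks within
    each facility, in record order (facility == trader here)."""
    counters: dict[str, int] = {}
    result: dict[str, str] = {}
    for rec in records:
        idx = counters.get(rec.facility_id, 0)
        counters[rec.facility_id] = idx + 1
        result[rec.tag] = f"{rec.facility_id}-C{idx // consignment_size + 1:02d}"
    return result


def _allocate_spot_checks(
    consignment_tags: dict[str, list[str]], spot_fraction: float, quota: int
) -> dict[str, int]:
    """Largest-remainder allocation of ceil(spot_fraction*quota) spot checks
    across consignments, at least one per consignment."""
    total = math.ceil(spot_fraction * quota)
    total = max(total, len(consignment_tags))
    quotas = {c: spot_fraction * len(tags) for c, tags in consignment_tags.items()}
    alloc = {c: max(1, math.floor(q)) for c, q in quotas.items()}
    alloc = {c: min(a, len(consignment_tags[c])) for c, a in alloc.items()}
    remainders = sorted(
        consignment_tags,
        key=lambda c: (-(quotas[c] - math.floor(quotas[c])), c),
    )
    i = 0
    while sum(alloc.values()) < total and i < 10 * len(remainders):
        c = remainders[i % len(remainders)]
        if alloc[c] < len(consignment_tags[c]):
            alloc[c] += 1
        i += 1
    return alloc


def simulate_cohort(
    config: CohortConfig,
    panels: tuple[SpeciesPanel, SpeciesPanel],
) -> tuple[list[Sample], list[Sample], TruthTable]:
    """Simulate the farm cohort, the port spot-check subset and the truth.

    Farm genotypes are drawn under Hardy–Weinberg from the lion panel,
    except planted anomalies. Port samples duplicate their source-farm
    genotype exactly (before genotyping error), except the planted
    reassigned/pooled classes. Genotyping error is applied after truth
    assignment. Fixed seed implies byte-identical output.
    """
    lion, tiger = panels
    rng = np.random.default_rng(config.seed)
    n = config.quota_size
    a = config.anomalies

    tags = [f"T{config.year}-{i + 1:04d}" for i in range(n)]
    facilities = [f"F{(i % config.n_facilities) + 1:02d}" for i in range(n)]
    # contiguous facility blocks: sort by facility for block structure
    order = sorted(range(n), key=lambda i: (facilities[i], i))
    facility_of = {tags[i]: facilities[i] for i in range(n)}

    # --- plant farm-level anomaly tags -------------------------------------
    shuffled = list(rng.permutation(tags))
    needed = a.non_target_species + 2 * a.duplicate_individual + a.reassigned_tag + a.pooled_no_match
    if needed > n:
        raise ValueError("anomaly counts exceed available tags")
    cursor = 0
    tiger_tags = shuffled[cursor: cursor + a.non_target_species]
    cursor += a.non_target_species
    dup_pairs: list[tuple[str, str]] = []
    for _ in range(a.duplicate_individual):
        t1, t2 = shuffled[cursor], shuffled[cursor + 1]
        cursor += 2
        dup_pairs.append((t1, t2))
    reassigned_tags = shuffled[cursor: cursor + a.reassigned_tag]
    cursor += a.reassigned_tag
    pooled_tags = shuffled[cursor: cursor + a.pooled_no_match]
    cursor += a.pooled_no_match

    # --- farm genotypes -----------------------------------------------------
    farm_truth: dict[str, FarmTruth] = {}
    geno_by_tag: dict[str, StrGenotype] = {}
    species_by_tag: dict[str, SpeciesLabel] = {}
    indiv_by_tag: dict[str, str] = {}
    indiv_counter = 0
    dup_source = {t2: t1 for (t1, t2) in dup_pairs}
    for tag in tags:
        if tag in dup_source:
            continue  # filled from its pair partner below
        indiv_counter += 1
        iid = f"I{indiv_counter:04d}"
        if tag in tiger_tags:
            geno = sample_genotype(tiger, rng)
            sp = SpeciesLabel.TIGER
            cls = "NON_TARGET_SPECIES"
        else:
            geno = sample_genotype(lion, rng)
            sp = SpeciesLabel.LION
            cls = "DUPLICATE_INDIVIDUAL" if any(tag == t1 for t1, _ in dup_pairs) else "NONE"
        geno_by_tag[tag] = geno
        species_by_tag[tag] = sp
        indiv_by_tag[tag] = iid
        farm_truth[tag] = FarmTruth(iid, sp, cls)
    for t1, t2 in dup_pairs:
        geno_by_tag[t2] = StrGenotype(dict(geno_by_tag[t1].alleles))
        species_by_tag[t2] = species_by_tag[t1]
        indiv_by_tag[t2] = indiv_by_tag[t1]
        farm_truth[t2] = FarmTruth(indiv_by_tag[t1], species_by_tag[t1], "DUPLICATE_INDIVIDUAL")

    farm_samples: list[Sample] = []
    farm_records: list[SampleRecord] = []
    for i in order:
        tag = tags[i]
        rec = SampleRecord(
            sample_id=f"FARM-{tag}",
            tag=tag,
            facility_id=facility_of[tag],
            site=Site.FARM,
            year=config.year,
            claimed_species="LION",
        )
        farm_records.append(rec)
        farm_samples.append(Sample(rec, geno_by_tag[tag], _snp_calls(species_by_tag[tag])))

    # --- spot-check selection ----------------------------------------------
    consignment_of = assign_consignments(farm_records, config.consignment_size)
    consignment_tags: dict[str, list[str]] = {}
    for rec in farm_records:
        consignment_tags.setdefault(consignment_of[rec.tag], []).append(rec.tag)
    alloc = _allocate_spot_checks(consignment_tags, config.spot_fraction, n)
    # the intercepted non-target skeleton never reaches the port spot-check
    blocked = set(tiger_tags)
    spot_tags: list[str] = []
    for cid in sorted(consignment_tags):
        eligible = [t for t in consignment_tags[cid] if t not in blocked]
        take = min(alloc[cid], len(eligible))
        chosen = rng.choice(len(eligible), size=take, replace=False)
        spot_tags.extend(eligible[i] for i in sorted(chosen))

    # port anomalies must land on spot-checked tags to be observable
    dup_tags = {t for pair in dup_pairs for t in pair}
    candidates = [t for t in spot_tags if t not in dup_tags]
    rng.shuffle(candidates)
    if a.reassigned_tag + a.pooled_no_match > len(candidates):
        raise ValueError("not enough spot-checked tags for planted port anomalies")
    port_reassigned = candidates[: a.reassigned_tag]
    port_pooled = candidates[a.reassigned_tag: a.reassigned_tag + a.pooled_no_match]

    port_truth: dict[str, PortTruth] = {}
    port_samples: list[Sample] = []
    ext_counter = 0
    for tag in spot_tags:
        rec = SampleRecord(
            sample_id=f"PORT-{tag}",
            tag=tag,
            facility_id=facility_of[tag],
            site=Site.PORT,
            year=config.year,
            claimed_species="LION",
        )
        if tag in port_reassigned:
            # genotype of a *different* individual from the same facility
            others = [
                t
                for t in tags
                if facility_of[t] == facility_of[tag]
                and indiv_by_tag[t] != indiv_by_tag[tag]
                and species_by_tag[t] is SpeciesLabel.LION
            ]
            src = others[int(rng.integers(len(others)))]
            geno = StrGenotype(dict(geno_by_tag[src].alleles))
            port_truth[tag] = PortTruth(indiv_by_tag[src], "REASSIGNED_TAG")
            sp = species_by_tag[src]
        elif tag in port_pooled:
            ext_counter += 1
            geno = sample_genotype(panels[0], rng)
            port_truth[tag] = PortTruth(
                f"X{ext_counter:03d}", "POOLED_NO_MATCH", externally_sourced=True
            )
            sp = SpeciesLabel.LION
        else:
            geno = StrGenotype(dict(geno_by_tag[tag].alleles))
            port_truth[tag] = PortTruth(indiv_by_tag[tag], "NONE")
            sp = species_by_tag[tag]
        port_samples.append(Sample(rec, geno, _snp_calls(sp)))

    # --- genotyping error (after truth assignment) --------------------------
    err = config.genotyping_error
    if err.dropout > 0 or err.false_allele > 0:
        for sample in farm_samples + port_samples:
            geno = sample.genotype
            for locus in geno.loci:
                pair = list(geno.pair(locus))
                if err.false_allele > 0 and rng.random() < err.false_allele:
                    table = lion.freqs[locus]
                    sizes = list(table.keys())
                    pair[int(rng.integers(2))] = int(
                        sizes[int(rng.integers(len(sizes)))]
                    )
                if err.dropout > 0:
                    for j in (0, 1):
                        if pair[j] != 0 and rng.random() < err.dropout:
                            pair[j] = 0
                geno.alleles[locus] = (min(pair), max(pair))

    return farm_samples, port_samples, TruthTable(farm_truth, port_truth)


# ---------------------------------------------------------------------------
# Weights
# ---------------------------------------------------------------------------

def simulate_weights(
    farm_samples: Sequence[Sample],
    weight_params: WeightParams,
    seed: int = 0,
    port_tags: Sequence[str] | None = None,
    consignment_of: Mapping[str, str] | None = None,
    inflate: Mapping[str, float] | None = None,
) -> list[WeightRecord]:
    """Weight manifest: truncated-normal farm weights; port nett weight is
    farm weight times a desiccation factor; gross adds packaging. Optional
    planted inflation (kg added to port gross) per tag."""
    wp = weight_params
    rng = np.random.default_rng(seed)
    port_set = set(port_tags) if port_tags is not None else set()
    inflate = dict(inflate or {})
    records: list[WeightRecord] = []
    for sample in farm_samples:
        tag = sample.record.tag
        farm_w = 0.0
        while True:  # truncated normal, lower bound strictly positive
            farm_w = rng.normal(wp.farm_mean, wp.farm_sd)
            if farm_w > wp.floor_kg:
                break
        port_gross = None
        packaging = None
        if tag in port_set:
            factor = rng.normal(wp.desiccation_mean, wp.desiccation_sd)
            factor = max(factor, 0.05)
            packaging = max(0.0, rng.normal(wp.packaging_mean, wp.packaging_sd))
            nett = farm_w * factor + inflate.get(tag, 0.0)
            port_gross = nett + packaging
        cid = consignment_of.get(tag, "") if consignment_of else ""
        records.append(
            WeightRecord(
                tag=tag,
                farm_weight_kg=float(farm_w),
                consignment_id=cid,
                trader_id=sample.record.facility_id,
                year=sample.record.year,
                port_gross_weight_kg=None if port_gross is None else float(port_gross),
                packaging_weight_kg=None if packaging is None else float(packaging),
            )
        )
    return records
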