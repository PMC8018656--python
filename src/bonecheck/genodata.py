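"""Domain types, file formats and chain-of-custody bookkeeping.

Tabular formats are plain UTF-8 CSV with strict parsing: any malformed
cell raises :class:`ParseError` carrying the (1-based) row and the column
name, so a compliance analyst can locate the offending record.

Conventions
-----------
* A microsatellite (STR) genotype is an unordered pair of integer allele
  sizes per locus, stored sorted ascending. Allele 0 denotes a missing
  call (GENEPOP convention); a locus is fully typed (two nonzero),
  missing (both zero), or half-called (exactly one zero — e.g. allelic
  dropout).
* Sites are ``FARM`` (source-facility inspection) and ``PORT`` (airport
  spot-check); matching the two verifies the exported skeleton is the
  permitted individual.
"""

from __future__ import annotations

import datetime
import enum
import hashlib
import json
import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence


class Site(str, enum.Enum):
    FARM = "FARM"
    PORT = "PORT"


class SpeciesLabel(str, enum.Enum):
    LION = "LION"
    TIGER = "TIGER"


class SkullCall(str, enum.Enum):
    LION = "LION"
    TIGER = "TIGER"
    NOT_ASSESSED = "NOT_ASSESSED"


class SnpAllele(str, enum.Enum):
    """Per-locus call at a fixed-difference mitochondrial SNP."""

    LION = "LION"
    TIGER = "TIGER"
    UNDETERMINED = "UNDETERMINED"


class ParseError(ValueError):
    """Malformed input cell, located by row (1-based, incl. header) and column."""

    def __init__(self, message: str, row: int | None = None, column: str | None = None):
        loc = ""
        if row is not None:
            loc += f" [row {row}"
            loc += f", column {column}]" if column is not None else "]"
        super().__init__(message + loc)
        self.row = row
        self.column = column


@dataclass(frozen=True)
class SampleRecord:
    """Chain-of-custody metadata binding a bone sample to a skeleton."""

    sample_id: str
    tag: str
    facility_id: str
    site: Site
    year: int
    claimed_species: str = "LION"
    skull_morphology_call: SkullCall = SkullCall.NOT_ASSESSED

    def key(self) -> tuple[str, Site, int]:
        return (self.tag, self.site, self.year)


@dataclass
class StrGenotype:
    """Unordered diploid allele pair per locus; pairs stored sorted ascending."""

    alleles: dict[str, tuple[int, int]]

    def __post_init__(self) -> None:
        fixed = {}
        for locus, pair in self.alleles.items():
            a, b = int(pair[0]), int(pair[1])
            if a < 0 or b < 0:
                raise ValueError(f"negative allele at {locus}: {pair}")
            fixed[locus] = (a, b) if a <= b else (b, a)
        self.alleles = fixed

    @property
    def loci(self) -> list[str]:
        return list(self.alleles)

    def pair(self, locus: str) -> tuple[int, int]:
        return self.alleles[locus]

    def is_typed(self, locus: str) -> bool:
        a, b = self.alleles[locus]
        return a > 0 and b > 0

    def is_missing(self, locus: str) -> bool:
        a, b = self.alleles[locus]
        return a == 0 and b == 0

    def is_half_called(self, locus: str) -> bool:
        a, b = self.alleles[locus]
        return (a == 0) != (b == 0)

    def typed_loci(self) -> list[str]:
        return [l for l in self.alleles if self.is_typed(l)]


@dataclass
class SnpCallSet:
    """Calls at the diagnostic mtDNA loci (control region, 12S, 16S)."""

    calls: dict[str, SnpAllele]

    def loci(self) -> list[str]:
        return list(self.calls)


@dataclass
class WeightRecord:
    tag: str
    farm_weight_kg: float
    consignment_id: str = ""
    trader_id: str = ""
    year: int = 0
    port_gross_weight_kg: float | None = None
    packaging_weight_kg: float | None = None

    def __post_init__(self) -> None:
        if self.farm_weight_kg <= 0:
            raise ValueError(f"farm weight must be positive (tag {self.tag})")
        if self.port_gross_weight_kg is not None and self.port_gross_weight_kg <= 0:
            raise ValueError(f"port gross weight must be positive (tag {self.tag})")
        if self.packaging_weight_kg is not None and self.packaging_weight_kg < 0:
            raise ValueError(f"packaging weight must be non-negative (tag {self.tag})")

    @property
    def port_nett_kg(self) -> float | None:
        if self.port_gross_weight_kg is None:
            return None
        if self.packaging_weight_kg is None:
            return None
        return self.port_gross_weight_kg - self.packaging_weight_kg


_META_COLUMNS = ["sample_id", "tag", "facility_id", "site", "year", "claimed_species"]


def _locus_columns(loci: Sequence[str]) -> list[str]:
    cols = []
    for locus in loci:
        cols.append(f"{locus}.1")
        cols.append(f"{locus}.2")
    return cols


def write_genotype_table(
    records: Sequence[SampleRecord],
    genotypes: Sequence[StrGenotype],
    path: str | Path,
) -> None:
    """Write aligned records+genotypes as CSV; deterministic byte output."""
    if len(records) != len(genotypes):
        raise ValueError(
            f"records ({len(records)}) and genotypes ({len(genotypes)}) misaligned"
        )
    loci: list[str] = genotypes[0].loci if genotypes else []
    for g in genotypes:
        if g.loci != loci:
            raise ValueError("all genotypes must share the same locus set and order")
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(_META_COLUMNS + _locus_columns(loci))
        for rec, geno in zip(records, genotypes):
            row = [
                rec.sample_id,
                rec.tag,
                rec.facility_id,
                rec.site.value,
                str(rec.year),
                rec.claimed_species,
            ]
            for locus in loci:
                a, b = geno.pair(locus)
                row.extend([str(a), str(b)])
            writer.writerow(row)


def read_genotype_table(path: str | Path) -> tuple[list[SampleRecord], list[StrGenotype]]:
    """Strict parse of the genotype CSV; raises located :class:`ParseError`."""
    path = Path(path)
    with path.open("r", newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError(f"{path}: missing header") from None
        if header[: len(_META_COLUMNS)] != _META_COLUMNS:
            raise ParseError(
                f"{path}: header must start with {','.join(_META_COLUMNS)}", row=1
            )
        locus_cols = header[len(_META_COLUMNS):]
        if len(locus_cols) % 2 != 0:
            raise ParseError(f"{path}: odd number of allele columns", row=1)
        loci = []
        for i in range(0, len(locus_cols), 2):
            c1, c2 = locus_cols[i], locus_cols[i + 1]
            if not (c1.endswith(".1") and c2.endswith(".2") and c1[:-2] == c2[:-2]):
                raise ParseError(
                    f"{path}: allele columns must come in LOCUS.1/LOCUS.2 pairs "
                    f"(got {c1!r}, {c2!r})",
                    row=1,
                    column=c1,
                )
            loci.append(c1[:-2])

        records: list[SampleRecord] = []
        genotypes: list[StrGenotype] = []
        seen_keys: set[tuple[str, Site, int]] = set()
        for rownum, row in enumerate(reader, start=2):
            if len(row) != len(header):
                raise ParseError(
                    f"{path}: ragged row ({len(row)} cells, expected {len(header)})",
                    row=rownum,
                )
            sample_id, tag, facility_id, site_s, year_s, claimed = row[:6]
            try:
                site = Site(site_s)
            except ValueError:
                raise ParseError(
                    f"{path}: unknown site {site_s!r}", row=rownum, column="site"
                ) from None
            try:
                year = int(year_s)
            except ValueError:
                raise ParseError(
                    f"{path}: non-integer year {year_s!r}", row=rownum, column="year"
                ) from None
            rec = SampleRecord(sample_id, tag, facility_id, site, year, claimed)
            if rec.key() in seen_keys:
                raise ParseError(
                    f"{path}: duplicate (tag, site, year) {rec.key()}", row=rownum
                )
            seen_keys.add(rec.key())
            alleles: dict[str, tuple[int, int]] = {}
            for i, locus in enumerate(loci):
                cells = row[6 + 2 * i: 8 + 2 * i]
                pair = []
                for j, cell in enumerate(cells):
                    try:
                        val = int(cell)
                    except ValueError:
                        raise ParseError(
                            f"{path}: non-integer allele {cell!r}",
                            row=rownum,
                            column=f"{locus}.{j + 1}",
                        ) from None
                    if val < 0:
                        raise ParseError(
                            f"{path}: negative allele {val}",
                            row=rownum,
                            column=f"{locus}.{j + 1}",
                        )
                    pair.append(val)
                alleles[locus] = (pair[0], pair[1])
            records.append(rec)
            genotypes.append(StrGenotype(alleles))
    return records, genotypes


def write_snp_table(
    records: Sequence[SampleRecord],
    call_sets: Sequence[SnpCallSet],
    path: str | Path,
) -> None:
    if len(records) != len(call_sets):
        raise ValueError("records and SNP call sets misaligned")
    loci = call_sets[0].loci() if call_sets else []
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["sample_id", "tag", "site", "year"] + loci)
        for rec, cs in zip(records, call_sets):
            if cs.loci() != loci:
                raise ValueError("all SNP call sets must share the same loci")
            writer.writerow(
                [rec.sample_id, rec.tag, rec.site.value, str(rec.year)]
                + [cs.calls[l].value for l in loci]
            )


def read_snp_table(path: str | Path) -> tuple[list[dict], list[SnpCallSet]]:
    """Parse the SNP call CSV; returns row metadata dicts and call sets."""
    path = Path(path)
    with path.open("r", newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError(f"{path}: missing header") from None
        meta_cols = ["sample_id", "tag", "site", "year"]
        if header[:4] != meta_cols:
            raise ParseError(f"{path}: header must start with {','.join(meta_cols)}", row=1)
        loci = header[4:]
        metas, call_sets = [], []
        for rownum, row in enumerate(reader, start=2):
            if len(row) != len(header):
                raise ParseError(f"{path}: ragged row", row=rownum)
            try:
                year = int(row[3])
            except ValueError:
                raise ParseError(
                    f"{path}: non-integer year {row[3]!r}", row=rownum, column="year"
                ) from None
            calls = {}
            for locus, cell in zip(loci, row[4:]):
                try:
                    calls[locus] = SnpAllele(cell)
                except ValueError:
                    raise ParseError(
                        f"{path}: unknown SNP call {cell!r}", row=rownum, column=locus
                    ) from None
            metas.append(
                {"sample_id": row[0], "tag": row[1], "site": Site(row[2]), "year": year}
            )
            call_sets.append(SnpCallSet(calls))
    return metas, call_sets


_WEIGHT_COLUMNS = [
    "tag",
    "facility_id",
    "consignment_id",
    "trader_id",
    "year",
    "farm_weight_kg",
    "port_gross_weight_kg",
    "packaging_weight_kg",
]


def write_weight_table(records: Sequence[WeightRecord], path: str | Path,
                       facility_by_tag: Mapping[str, str] | None = None) -> None:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(_WEIGHT_COLUMNS)
        for rec in records:
            fac = facility_by_tag.get(rec.tag, "") if facility_by_tag else ""
            writer.writerow(
                [
                    rec.tag,
                    fac,
                    rec.consignment_id,
                    rec.trader_id,
                    str(rec.year),
                    repr(rec.farm_weight_kg),
                    "" if rec.port_gross_weight_kg is None else repr(rec.port_gross_weight_kg),
                    "" if rec.packaging_weight_kg is None else repr(rec.packaging_weight_kg),
                ]
            )


def read_weight_table(path: str | Path) -> list[WeightRecord]:
    path = Path(path)
    out: list[WeightRecord] = []
    with path.open("r", newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError(f"{path}: missing header") from None
        if header != _WEIGHT_COLUMNS:
            raise ParseError(f"{path}: unexpected weight-table header", row=1)
        for rownum, row in enumerate(reader, start=2):
            if len(row) != len(header):
                raise ParseError(f"{path}: ragged row", row=rownum)
            def _float(cell: str, col: str) -> float | None:
                if cell == "":
                    return None
                try:
                    return float(cell)
                except ValueError:
                    raise ParseError(
                        f"{path}: non-numeric weight {cell!r}", row=rownum, column=col
                    ) from None
            try:
                year = int(row[4])
            except ValueError:
                raise ParseError(
                    f"{path}: non-integer year {row[4]!r}", row=rownum, column="year"
                ) from None
            farm_w = _float(row[5], "farm_weight_kg")
            if farm_w is None:
                raise ParseError(
                    f"{path}: farm weight required", row=rownum, column="farm_weight_kg"
                )
            out.append(
                WeightRecord(
                    tag=row[0],
                    farm_weight_kg=farm_w,
                    consignment_id=row[2],
                    trader_id=row[3],
                    year=year,
                    port_gross_weight_kg=_float(row[6], "port_gross_weight_kg"),
                    packaging_weight_kg=_float(row[7], "packaging_weight_kg"),
                )
            )
    return out


def export_genepop(
    records: Sequence[SampleRecord],
    genotypes: Sequence[StrGenotype],
    path: str | Path,
    title: str = "bonecheck export",
) -> None:
    """Write a GENEPOP-dialect file: three-digit allele coding, 000 missing,
    one ``Pop`` block per facility (input order of first appearance)."""
    if len(records) != len(genotypes):
        raise ValueError("records and genotypes misaligned")
    loci = genotypes[0].loci if genotypes else []
    for g in genotypes:
        for locus in loci:
            a, b = g.pair(locus)
            if a > 999 or b > 999:
                raise ValueError(
                    f"allele size > 999 at {locus} cannot be GENEPOP three-digit coded"
                )
    # group by facility preserving first-appearance order
    order: list[str] = []
    groups: dict[str, list[int]] = {}
    for idx, rec in enumerate(records):
        if rec.facility_id not in groups:
            groups[rec.facility_id] = []
            order.append(rec.facility_id)
        groups[rec.facility_id].append(idx)
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write(title + "\n")
        for locus in loci:
            fh.write(locus + "\n")
        for fac in order:
            fh.write("Pop\n")
            for idx in groups[fac]:
                rec, geno = records[idx], genotypes[idx]
                cells = []
                for locus in loci:
                    a, b = geno.pair(locus)
                    cells.append(f"{a:03d}{b:03d}")
                fh.write(f"{rec.sample_id} ,  " + " ".join(cells) + "\n")


def custody_digest(paths: Iterable[str | Path]) -> dict:
    """SHA-256 manifest over evidence files.

    Digests are stable across reruns on unchanged files; the manifest also
    records a generation timestamp (excluded from deterministic reports).
    """
    files = {}
    for p in paths:
        p = Path(p)
        h = hashlib.sha256()
        with p.open("rb") as fh:
            for chunk in iter(lambda: fh.read(65536), b""):
                h.update(chunk)
        files[p.name] = {"sha256": h.hexdigest(), "bytes": p.stat().st_size}
    return {
        "files": files,
        "generated_at": datetime.datetime.now(datetime.timezone.utc).isoformat(),
    }


def write_custody_manifest(digest: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(digest, indent=2, sort_keys=True) + "\n", encoding="utf-8")
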