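"""Farm-to-port individual matching and anomaly classification.

The forensic core of the compliance audit. Each port spot-check sample
is compared against the full farm cohort of its year by Queller–Goodnight
pairwise relatedness; the same-tag farm sample should stand out as an
extreme upper outlier (r = 1 for an identical genotype). Significance is
assessed with the generalized extreme studentized deviate (ESD, Rosner)
test over the port sample's relatedness distribution to all farm samples
of that year. Detected irregularities are classified into the two broad
causes seen in quota audits: bone mixing / pooling (Type I) and
mislabelling / tag-swapping (Type II).

Queller–Goodnight estimator (per locus, x = {a,b}, y = {c,d}, reference
frequencies p):

    num_x = 0.5*(d_ac + d_ad + d_bc + d_bd) - p_a - p_b
    den_x = 1 + d_ab - p_a - p_b
    r_xy  = sum_loci num_x / sum_loci den_x        (ratio of sums)
    r     = (r_xy + r_yx) / 2                      (symmetrized)

Loci where both directional denominators vanish carry no information and
are skipped. The ratio-of-sums combination avoids the per-locus
zero-denominator pathology. For identical genotypes num_x equals den_x
algebraically at every locus, so r = 1 exactly.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .genodata import SampleRecord, StrGenotype
from .species import FinalCall, SpeciesAssignment
from .synth import Sample

__all__ = [
    "MatchParams",
    "MatchClass",
    "MatchResult",
    "EsdResult",
    "DuplicatePair",
    "AnomalyLedger",
    "TagAbsentError",
    "cohort_frequencies",
    "qg_relatedness",
    "relatedness_matrix",
    "esd_outliers",
    "match_port_sample",
    "match_cohort",
    "find_duplicates",
    "classify_anomalies",
]


class TagAbsentError(KeyError):
    """A port sample's declared tag has no farm sample in the cohort."""


class MatchClass(str, enum.Enum):
    MATCH = "MATCH"
    REASSIGNED_SAME_FARM = "REASSIGNED_SAME_FARM"
    NO_MATCH = "NO_MATCH"
    NON_TARGET_SPECIES = "NON_TARGET_SPECIES"
    PENDING = "PENDING"


@dataclass(frozen=True)
class MatchParams:
    alpha: float = 0.05
    k_max: int = 5  # a port sample has at most a handful of near-identical relatives
    r_identity_floor: float = 0.9  # separates same-individual from close kin (full sibs r~0.5)


@dataclass
class MatchResult:
    port_sample_id: str
    declared_tag: str
    match_class: MatchClass
    matched_farm_sample: str | None = None
    best_farm_tag: str | None = None
    matched_facility: str | None = None
    cross_facility: bool = False
    esd_significant: bool = False
    r_same_tag: float = float("nan")
    r_best: float = float("nan")


# ---------------------------------------------------------------------------
# Relatedness
# ---------------------------------------------------------------------------

def cohort_frequencies(
    genotypes: Sequence[StrGenotype],
) -> dict[str, dict[int, float]]:
    """Reference allele frequencies from a cohort (no dyad exclusion)."""
    counts: dict[str, dict[int, int]] = {}
    totals: dict[str, int] = {}
    for g in genotypes:
        for locus in g.loci:
            if not g.is_typed(locus):
                continue
            tab = counts.setdefault(locus, {})
            for a in g.pair(locus):
                tab[a] = tab.get(a, 0) + 1
            totals[locus] = totals.get(locus, 0) + 2
    return {
        locus: {a: c / totals[locus] for a, c in sorted(tab.items())}
        for locus, tab in counts.items()
    }


def qg_relatedness(
    x: StrGenotype,
    y: StrGenotype,
    reference_freqs: Mapping[str, Mapping[int, float]],
) -> float:
    """Symmetrized Queller–Goodnight relatedness between two genotypes."""
    num_x = den_x = num_y = den_y = 0.0
    informative = 0
    for locus, freqs in reference_freqs.items():
        if locus not in x.alleles or locus not in y.alleles:
            continue
        if not (x.is_typed(locus) and y.is_typed(locus)):
            continue
        a, b = x.pair(locus)
        c, d = y.pair(locus)
        pa, pb = freqs.get(a, 0.0), freqs.get(b, 0.0)
        pc, pd = freqs.get(c, 0.0), freqs.get(d, 0.0)
        share = 0.5 * ((a == c) + (a == d) + (b == c) + (b == d))
        nx = share - pa - pb
        dx = 1.0 + (a == b) - pa - pb
        ny = share - pc - pd
        dy = 1.0 + (c == d) - pc - pd
        if dx == 0.0 and dy == 0.0:
            continue
        informative += 1
        num_x += nx
        den_x += dx
        num_y += ny
        den_y += dy
    if informative == 0:
        raise ValueError("no informative loci for relatedness")
    # a direction whose denominator sum vanishes (e.g. a heterozygote whose
    # alleles exhaust the frequency mass at every locus) is uninformative;
    # fall back to the defined direction alone
    if den_x == 0.0 and den_y == 0.0:
        raise ValueError("no informative loci for relatedness")
    if den_x == 0.0:
        return num_y / den_y
    if den_y == 0.0:
        return num_x / den_x
    return 0.5 * (num_x / den_x + num_y / den_y)


def _encode(
    genotypes: Sequence[StrGenotype],
    loci: Sequence[str],
    freqs: Mapping[str, Mapping[int, float]],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Allele matrix (n, L, 2), matching frequency matrix, typed mask."""
    n, L = len(genotypes), len(loci)
    alleles = np.zeros((n, L, 2), dtype=np.int64)
    p = np.zeros((n, L, 2), dtype=np.float64)
    typed = np.zeros((n, L), dtype=bool)
    for i, g in enumerate(genotypes):
        for j, locus in enumerate(loci):
            if locus not in g.alleles:
                continue
            a, b = g.pair(locus)
            alleles[i, j] = (a, b)
            typed[i, j] = a > 0 and b > 0
            tab = freqs[locus]
            p[i, j] = (tab.get(a, 0.0), tab.get(b, 0.0))
    return alleles, p, typed


def relatedness_matrix(
    rows: Sequence[StrGenotype],
    cols: Sequence[StrGenotype],
    reference_freqs: Mapping[str, Mapping[int, float]],
) -> np.ndarray:
    """Pairwise symmetrized Queller–Goodnight r, rows x cols (vectorized;
    identical semantics to :func:`qg_relatedness`)."""
    loci = [l for l in reference_freqs]
    ax, px, tx = _encode(rows, loci, reference_freqs)
    ay, py, ty = _encode(cols, loci, reference_freqs)
    # allele sharing: sum over the four cross comparisons
    share = (
        (ax[:, None, :, :, None] == ay[None, :, :, None, :]).sum(axis=(3, 4)) * 0.5
    )  # (nx, ny, L)
    psum_x = px.sum(axis=2)  # (nx, L)
    psum_y = py.sum(axis=2)
    hom_x = ax[:, :, 0] == ax[:, :, 1]
    hom_y = ay[:, :, 0] == ay[:, :, 1]
    den_x = 1.0 + hom_x - psum_x  # (nx, L)
    den_y = 1.0 + hom_y - psum_y
    valid = tx[:, None, :] & ty[None, :, :]
    both_zero = (den_x[:, None, :] == 0.0) & (den_y[None, :, :] == 0.0)
    valid &= ~both_zero
    num_x = share - psum_x[:, None, :]
    num_y = share - psum_y[None, :, :]
    sum_num_x = np.where(valid, num_x, 0.0).sum(axis=2)
    sum_den_x = (valid * den_x[:, None, :]).sum(axis=2)
    sum_num_y = np.where(valid, num_y, 0.0).sum(axis=2)
    sum_den_y = (valid * den_y[None, :, :]).sum(axis=2)
    n_informative = valid.sum(axis=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        rx = sum_num_x / sum_den_x
        ry = sum_num_y / sum_den_y
        r = 0.5 * (rx + ry)
        # one-sided fallback where a directional denominator sum vanishes
        r = np.where((sum_den_x == 0.0) & (sum_den_y != 0.0), ry, r)
        r = np.where((sum_den_y == 0.0) & (sum_den_x != 0.0), rx, r)
    r[(n_informative == 0) | ((sum_den_x == 0.0) & (sum_den_y == 0.0))] = np.nan
    return r


# ---------------------------------------------------------------------------
# Generalized ESD (Rosner) outlier test
# ---------------------------------------------------------------------------

@dataclass
class EsdResult:
    flagged: list[int]          # original indices, in removal order
    removed_order: list[int]    # candidate removal order (length = steps run)
    R: list[float]              # test statistics R_i
    lam: list[float]            # critical values lambda_i

    @property
    def n_outliers(self) -> int:
        return len(self.flagged)


def esd_lambda(n: int, i: int, alpha: float) -> float:
    """Critical value lambda_i for the i-th ESD step (i >= 1)."""
    p = 1.0 - alpha / (2.0 * (n - i + 1))
    df = n - i - 1
    t = stats.t.ppf(p, df)
    return (n - i) * t / np.sqrt((df + t * t) * (n - i + 1))


def esd_outliers(
    values: Sequence[float], k_max: int = 5, alpha: float = 0.05
) -> EsdResult:
    """Rosner's generalized extreme studentized deviate procedure.

    Iteratively removes the value with the largest |x - mean|/sd; the
    largest step i with R_i > lambda_i fixes the flagged set (the first
    i removed values). Zero variance at any step stops the procedure.
    """
    x = np.asarray(values, dtype=float)
    n = len(x)
    if n < 3:
        raise ValueError("ESD requires n >= 3")
    if k_max >= n / 2:
        raise ValueError("k_max must be < n/2")
    remaining = np.arange(n)
    work = x.copy()
    R: list[float] = []
    lam: list[float] = []
    removal: list[int] = []
    for i in range(1, k_max + 1):
        mean = work.mean()
        sd = work.std(ddof=1)
        if sd == 0.0:
            break
        dev = np.abs(work - mean)
        j = int(np.argmax(dev))
        R.append(float(dev[j] / sd))
        lam.append(float(esd_lambda(n, i, alpha)))
        removal.append(int(remaining[j]))
        work = np.delete(work, j)
        remaining = np.delete(remaining, j)
    n_out = 0
    for i in range(len(R)):
        if R[i] > lam[i]:
            n_out = i + 1
    return EsdResult(flagged=removal[:n_out], removed_order=removal, R=R, lam=lam)


# ---------------------------------------------------------------------------
# Matching
# ---------------------------------------------------------------------------

def _match_from_row(
    port_record: SampleRecord,
    farm_records: Sequence[SampleRecord],
    r_row: np.ndarray,
    params: MatchParams,
) -> MatchResult:
    tag_index = {rec.tag: i for i, rec in enumerate(farm_records)}
    if port_record.tag not in tag_index:
        raise TagAbsentError(
            f"declared tag {port_record.tag!r} absent from farm cohort"
        )
    same_idx = tag_index[port_record.tag]
    esd = esd_outliers(r_row, k_max=params.k_max, alpha=params.alpha)
    mean_r = float(np.mean(r_row))
    # only upper-tail flags can be matches
    candidates = [i for i in esd.flagged if r_row[i] > mean_r]
    r_same = float(r_row[same_idx])
    best_idx = int(np.argmax(r_row))
    r_best = float(r_row[best_idx])
    result = MatchResult(
        port_sample_id=port_record.sample_id,
        declared_tag=port_record.tag,
        match_class=MatchClass.PENDING,
        r_same_tag=r_same,
        r_best=r_best,
        best_farm_tag=farm_records[best_idx].tag,
    )
    if same_idx in candidates and r_same >= r_best - 1e-12:
        result.match_class = MatchClass.MATCH
        result.matched_farm_sample = farm_records[same_idx].sample_id
        result.matched_facility = farm_records[same_idx].facility_id
        result.esd_significant = True
        return result
    others = [
        i for i in candidates if i != same_idx and r_row[i] >= params.r_identity_floor
    ]
    if others:
        j = max(others, key=lambda i: r_row[i])
        result.match_class = MatchClass.REASSIGNED_SAME_FARM
        result.matched_farm_sample = farm_records[j].sample_id
        result.best_farm_tag = farm_records[j].tag
        result.matched_facility = farm_records[j].facility_id
        result.cross_facility = (
            farm_records[j].facility_id != port_record.facility_id
        )
        result.esd_significant = True
        result.r_best = float(r_row[j])
        return result
    result.match_class = MatchClass.NO_MATCH
    return result


def match_port_sample(
    port_sample: Sample,
    farm_cohort: Sequence[Sample],
    reference_freqs: Mapping[str, Mapping[int, float]] | None = None,
    params: MatchParams = MatchParams(),
) -> MatchResult:
    """Match one port sample against the farm cohort of its year."""
    farm = [s for s in farm_cohort if s.record.year == port_sample.record.year]
    if len(farm) < 10:
        raise ValueError("farm cohort must contain >= 10 samples of the port year")
    if reference_freqs is None:
        reference_freqs = cohort_frequencies([s.genotype for s in farm])
    r_row = relatedness_matrix(
        [port_sample.genotype], [s.genotype for s in farm], reference_freqs
    )[0]
    return _match_from_row(
        port_sample.record, [s.record for s in farm], r_row, params
    )


def match_cohort(
    port_samples: Sequence[Sample],
    farm_cohort: Sequence[Sample],
    reference_freqs: Mapping[str, Mapping[int, float]] | None = None,
    params: MatchParams = MatchParams(),
    exclude_port_ids: set[str] | None = None,
    errors: list[str] | None = None,
) -> tuple[list[MatchResult], np.ndarray]:
    """Match every port sample; returns results plus the full relatedness
    matrix (port x farm). Port samples in `exclude_port_ids` (e.g. non-lion,
    handled upstream) are reported as NON_TARGET_SPECIES. If `errors` is a
    list, per-sample tag-absence errors are collected there (and the sample
    skipped) instead of raised."""
    if reference_freqs is None:
        reference_freqs = cohort_frequencies([s.genotype for s in farm_cohort])
    rmat = relatedness_matrix(
        [s.genotype for s in port_samples],
        [s.genotype for s in farm_cohort],
        reference_freqs,
    )
    farm_records = [s.record for s in farm_cohort]
    results = []
    for i, port in enumerate(port_samples):
        if exclude_port_ids and port.record.sample_id in exclude_port_ids:
            results.append(
                MatchResult(
                    port_sample_id=port.record.sample_id,
                    declared_tag=port.record.tag,
                    match_class=MatchClass.NON_TARGET_SPECIES,
                )
            )
            continue
        try:
            results.append(_match_from_row(port.record, farm_records, rmat[i], params))
        except TagAbsentError as exc:
            if errors is None:
                raise
            errors.append(str(exc.args[0]))
    return results, rmat


# ---------------------------------------------------------------------------
# Duplicates
# ---------------------------------------------------------------------------

@dataclass
class DuplicatePair:
    tag_a: str
    tag_b: str
    n_mismatch: int
    r: float = float("nan")


def find_duplicates(
    farm_cohort: Sequence[Sample],
    mismatch_tolerance: int = 0,
    reference_freqs: Mapping[str, Mapping[int, float]] | None = None,
) -> list[DuplicatePair]:
    """Farm tag pairs whose genotypes disagree at <= `mismatch_tolerance`
    loci (tolerance absorbs allelic dropout); evidence weight is the
    pairwise relatedness under the cohort frequencies."""
    if len(farm_cohort) < 2:
        return []
    loci = farm_cohort[0].genotype.loci
    arr = np.array(
        [[g.genotype.pair(l) for l in loci] for g in farm_cohort], dtype=np.int64
    )  # (n, L, 2)
    n = len(farm_cohort)
    pairs: list[tuple[int, int, int]] = []
    if mismatch_tolerance == 0:
        groups: dict[bytes, list[int]] = {}
        for i in range(n):
            groups.setdefault(arr[i].tobytes(), []).append(i)
        for idxs in groups.values():
            for a in range(len(idxs)):
                for b in range(a + 1, len(idxs)):
                    pairs.append((idxs[a], idxs[b], 0))
    else:
        for i in range(n - 1):
            diff = (arr[i + 1:] != arr[i][None]).any(axis=2).sum(axis=1)
            hits = np.flatnonzero(diff <= mismatch_tolerance)
            for h in hits:
                pairs.append((i, i + 1 + int(h), int(diff[h])))
    if reference_freqs is None:
        reference_freqs = cohort_frequencies([s.genotype for s in farm_cohort])
    out = []
    for i, j, nm in pairs:
        try:
            r = qg_relatedness(
                farm_cohort[i].genotype, farm_cohort[j].genotype, reference_freqs
            )
        except ValueError:
            r = float("nan")
        out.append(
            DuplicatePair(farm_cohort[i].record.tag, farm_cohort[j].record.tag, nm, r)
        )
    return out


# ---------------------------------------------------------------------------
# Anomaly classification (Type I pooling vs Type II mislabelling)
# ---------------------------------------------------------------------------

TYPE_I = "TYPE_I_POOLING"
TYPE_II = "TYPE_II_MISLABEL"
UNRESOLVED = "UNRESOLVED"


@dataclass
class AnomalyEntry:
    site: str
    year: int
    tag: str
    anomaly: str
    interpretation: str


@dataclass
class AnomalyLedger:
    entries: list[AnomalyEntry]
    duplicates: list[DuplicatePair]
    counts: dict[str, dict]  # "SITE/year" -> {n_anomalies, n_total, proportion}

    def summary_lines(self) -> list[str]:
        lines = []
        for key, c in sorted(self.counts.items()):
            pct = 100.0 * c["proportion"]
            lines.append(
                f"{key}: {c['n_anomalies']}/{c['n_total']} ({pct:.1f}%) anomalies"
            )
        return lines


def classify_anomalies(
    match_results: Sequence[MatchResult],
    duplicates: Sequence[DuplicatePair],
    species_assignments: Sequence[SpeciesAssignment],
    farm_records: Sequence[SampleRecord],
    port_records: Sequence[SampleRecord],
) -> AnomalyLedger:
    """Build the per-site/year anomaly ledger.

    Interpretation rules: a port sample matching a *different* tag
    (mislabelling / tag-swapping) is Type II; a port sample with no match
    in the farm cohort, and farm tag pairs sharing one genotype, indicate
    bone pooling and are Type I. Non-target species are counted
    separately (they are interceptions, not sampling irregularities of
    either type).
    """
    if any(m.match_class is MatchClass.PENDING for m in match_results):
        raise ValueError("all port samples must be resolved before classification")
    year_farm = {}
    for rec in farm_records:
        year_farm.setdefault(rec.year, 0)
        year_farm[rec.year] += 1
    year_port = {}
    for rec in port_records:
        year_port.setdefault(rec.year, 0)
        year_port[rec.year] += 1
    rec_by_sample = {r.sample_id: r for r in list(farm_records) + list(port_records)}
    farm_year_of = {r.tag: r.year for r in farm_records}
    port_year_of = {r.tag: r.year for r in port_records}

    entries: list[AnomalyEntry] = []
    for m in match_results:
        year = port_year_of.get(m.declared_tag, 0)
        if m.match_class is MatchClass.REASSIGNED_SAME_FARM:
            entries.append(
                AnomalyEntry("PORT", year, m.declared_tag, "REASSIGNED_TAG", TYPE_II)
            )
        elif m.match_class is MatchClass.NO_MATCH:
            entries.append(
                AnomalyEntry("PORT", year, m.declared_tag, "POOLED_NO_MATCH", TYPE_I)
            )
        elif m.match_class is MatchClass.NON_TARGET_SPECIES:
            entries.append(
                AnomalyEntry(
                    "PORT", year, m.declared_tag, "NON_TARGET_SPECIES", UNRESOLVED
                )
            )
    for dup in duplicates:
        year = farm_year_of.get(dup.tag_a, 0)
        for tag in (dup.tag_a, dup.tag_b):
            entries.append(
                AnomalyEntry("FARM", year, tag, "DUPLICATE_INDIVIDUAL", TYPE_I)
            )
    # non-target species detected among farm samples
    farm_ids = {r.sample_id for r in farm_records}
    for sa in species_assignments:
        if sa.final_call is FinalCall.LION:
            continue
        rec = rec_by_sample.get(sa.sample_id)
        if rec is None or rec.sample_id not in farm_ids:
            continue
        entries.append(
            AnomalyEntry(
                "FARM", rec.year, rec.tag, "NON_TARGET_SPECIES", UNRESOLVED
            )
        )

    counts: dict[str, dict] = {}
    for year, total in year_farm.items():
        n = sum(1 for e in entries if e.site == "FARM" and e.year == year)
        counts[f"FARM/{year}"] = {
            "n_anomalies": n,
            "n_total": total,
            "proportion": n / total if total else 0.0,
        }
    for year, total in year_port.items():
        n = sum(1 for e in entries if e.site == "PORT" and e.year == year)
        counts[f"PORT/{year}"] = {
            "n_anomalies": n,
            "n_total": total,
            "proportion": n / total if total else 0.0,
        }
    return AnomalyLedger(entries=entries, duplicates=list(duplicates), counts=counts)
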