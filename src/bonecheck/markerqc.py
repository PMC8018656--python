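"""Marker-panel validation statistics for forensic individualization.

Per-locus summaries certify the discriminatory power of an STR panel:
allele counts, heterozygosity, polymorphic information content (PIC),
probability of identity (PID), parentage exclusion probabilities, a
null-allele estimate, an exact Hardy–Weinberg test, and a linkage
disequilibrium permutation test. Cumulative PID across loci quantifies
the chance that two unrelated individuals share a full profile.

Formulas (p_i are allele frequencies at one locus, a_k = sum_i p_i^k):

* effective alleles      A_e  = 1 / a_2
* expected heterozygosity H_E = 1 - a_2      (uncorrected; an optional
  2n/(2n-1) small-sample correction is available but breaks the exact
  PIC <= H_E identity, so it is off by default)
* PIC = 1 - a_2 - sum_{i<j} 2 p_i^2 p_j^2
* PID = a_4 + sum_{i<j} (2 p_i p_j)^2
* null-allele frequency (Chakraborty): max(0, (H_E - H_O)/(H_E + H_O))
* exclusion probabilities, defined operationally:
    Pe1 — probability a random unrelated candidate parent is excluded
          when the other true parent is known;
    Pe2 — probability a random unrelated candidate *pair* is excluded
          as the parents of a random offspring.
  Both are computed by closed forms in power sums (verified against the
  genotype-configuration enumeration kept alongside as an oracle):
    Pe1 = 1 - 2a2 + a3 + 2a4 - 3a5 - 2a2^2 + 3a2a3
    Pe2 = 1 + 4a4 - 4a5 - 3a6 - 8a2^2 + 8a2a3 + 2a3^2
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .genodata import StrGenotype

__all__ = [
    "MarkerStats",
    "allele_frequencies",
    "locus_stats",
    "panel_summary",
    "write_marker_stats",
    "cumulative_pid",
    "exclusion_probabilities",
    "exclusion_probabilities_enum",
    "hwe_exact",
    "genotype_counts",
    "ld_permutation",
    "genotype_accumulation",
]


@dataclass
class MarkerStats:
    locus: str
    n_typed: int
    A_n: int
    A_e: float
    H_O: float
    H_E: float
    PIC: float
    PID: float
    Pe1: float
    Pe2: float
    null_freq: float
    monomorphic: bool = False
    hwe_p: float | None = None


def allele_frequencies(
    genotypes: Sequence[StrGenotype], locus: str
) -> dict[int, float]:
    """Allele frequencies over the 2n copies of fully typed individuals."""
    counts: dict[int, int] = {}
    total = 0
    for g in genotypes:
        if not g.is_typed(locus):
            continue
        for a in g.pair(locus):
            counts[a] = counts.get(a, 0) + 1
            total += 1
    if total == 0:
        raise ValueError(f"no fully typed individuals at locus {locus}")
    return {a: c / total for a, c in sorted(counts.items())}


def _power_sums(p: np.ndarray, kmax: int) -> list[float]:
    return [float(np.sum(p**k)) for k in range(kmax + 1)]


def exclusion_probabilities(freqs: Mapping[int, float] | np.ndarray) -> tuple[float, float]:
    """Closed-form Pe1 (one parent known) and Pe2 (parent pair)."""
    p = np.asarray(list(freqs.values()) if isinstance(freqs, Mapping) else freqs, float)
    a = _power_sums(p, 6)
    pe1 = 1 - 2 * a[2] + a[3] + 2 * a[4] - 3 * a[5] - 2 * a[2] ** 2 + 3 * a[2] * a[3]
    pe2 = (
        1 + 4 * a[4] - 4 * a[5] - 3 * a[6]
        - 8 * a[2] ** 2 + 8 * a[2] * a[3] + 2 * a[3] ** 2
    )
    return pe1, pe2


def exclusion_probabilities_enum(freqs: Mapping[int, float] | np.ndarray) -> tuple[float, float]:
    """Pe1/Pe2 by direct enumeration over parent–offspring genotype
    configurations — the operational definition; slow but authoritative."""
    p = np.asarray(list(freqs.values()) if isinstance(freqs, Mapping) else freqs, float)
    k = len(p)

    pe1 = 0.0
    for i in range(k):
        for j in range(k):
            pm = p[i] * p[j]
            for m in (i, j):  # maternal transmitted allele
                for f in range(k):  # true paternal allele
                    prob = 0.5 * pm * p[f]
                    off = sorted((m, f))
                    # alleles a candidate could have contributed given mother {i,j}
                    compat = set()
                    for c in range(k):
                        for a in (i, j):
                            if sorted((a, c)) == off:
                                compat.add(c)
                    q = sum(p[c] for c in compat)
                    pe1 += prob * (1.0 - q) ** 2

    def carries(a: int) -> float:
        return 1.0 - (1.0 - p[a]) ** 2

    def carries_both(a: int, b: int) -> float:
        if a == b:
            return carries(a)
        return (
            1.0 - (1.0 - p[a]) ** 2 - (1.0 - p[b]) ** 2 + (1.0 - p[a] - p[b]) ** 2
        )

    pe2 = 0.0
    for o1 in range(k):
        for o2 in range(k):
            prob = p[o1] * p[o2]
            e1 = carries(o1) * carries(o2)  # C1 gives o1, C2 gives o2
            e2 = carries(o2) * carries(o1)  # C1 gives o2, C2 gives o1
            both = carries_both(o1, o2) * carries_both(o2, o1)
            pe2 += prob * (1.0 - (e1 + e2 - both))
    return pe1, pe2


def locus_stats(
    genotypes: Sequence[StrGenotype],
    locus: str,
    unbiased_he: bool = False,
) -> MarkerStats:
    freqs = allele_frequencies(genotypes, locus)
    p = np.array(list(freqs.values()))
    typed = [g for g in genotypes if g.is_typed(locus)]
    n = len(typed)
    a2 = float(np.sum(p**2))
    a4 = float(np.sum(p**4))
    he = 1.0 - a2
    if unbiased_he and n > 0:
        he *= 2 * n / (2 * n - 1) if 2 * n > 1 else 1.0
    ho = sum(1 for g in typed if g.pair(locus)[0] != g.pair(locus)[1]) / n
    # cross terms sum_{i<j} x_i x_j = ((sum x)^2 - sum x^2)/2
    p2 = p**2
    cross_p2 = (float(np.sum(p2)) ** 2 - float(np.sum(p2**2))) / 2.0
    pic = 1.0 - a2 - 2.0 * cross_p2
    pp = np.outer(p, p)
    iu = np.triu_indices(len(p), k=1)
    pid = a4 + float(np.sum((2.0 * pp[iu]) ** 2))
    pe1, pe2 = exclusion_probabilities(p)
    mono = len(p) == 1
    if mono:
        null_freq = 0.0
    else:
        denom = he + ho
        null_freq = max(0.0, (he - ho) / denom) if denom > 0 else 0.0
    return MarkerStats(
        locus=locus,
        n_typed=n,
        A_n=len(p),
        A_e=1.0 / a2,
        H_O=ho,
        H_E=he,
        PIC=pic,
        PID=pid,
        Pe1=pe1,
        Pe2=pe2,
        null_freq=null_freq,
        monomorphic=mono,
    )


def cumulative_pid(stats: Sequence[MarkerStats]) -> float:
    """Multilocus probability of identity, assuming locus independence."""
    if not stats:
        raise ValueError("need at least one locus")
    out = 1.0
    for s in stats:
        out *= s.PID
    return out


def panel_summary(
    genotypes: Sequence[StrGenotype],
    loci: Sequence[str] | None = None,
    hwe_mc_reps: int = 0,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-locus statistics table (the panel-certification summary)."""
    if loci is None:
        loci = genotypes[0].loci
    rows = []
    for locus in loci:
        st = locus_stats(genotypes, locus)
        if hwe_mc_reps and st.A_n >= 2:
            st.hwe_p = hwe_exact(
                genotype_counts(genotypes, locus), mc_reps=hwe_mc_reps, seed=seed
            )
        rows.append(st.__dict__.copy())
    return pd.DataFrame(rows)


def write_marker_stats(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Hardy–Weinberg exact test (conditional on allele counts)
# ---------------------------------------------------------------------------

def genotype_counts(
    genotypes: Sequence[StrGenotype], locus: str
) -> dict[tuple[int, int], int]:
    counts: dict[tuple[int, int], int] = {}
    for g in genotypes:
        if g.is_typed(locus):
            pair = g.pair(locus)
            counts[pair] = counts.get(pair, 0) + 1
    return counts


def _table_logprob(occ: Mapping[tuple[int, int], int], margins: Sequence[int], n: int) -> float:
    """log conditional probability of a genotype table given allele counts
    (Levene): n! * 2^het * prod m_i! / ((2n)! * prod n_ij!)."""
    het = sum(c for (a, b), c in occ.items() if a != b)
    lp = (
        gammaln(n + 1)
        + het * math.log(2.0)
        + sum(gammaln(m + 1) for m in margins)
        - gammaln(2 * n + 1)
        - sum(gammaln(c + 1) for c in occ.values())
    )
    return float(lp)


def _enumerate_tables(margins: list[int], bound: int):
    """Yield all symmetric genotype tables with the given allele-count
    margins, as dicts {(i,j): count} with i<=j over allele indices.
    Raises OverflowError when more than `bound` tables exist."""
    k = len(margins)
    tables: list[dict[tuple[int, int], int]] = []

    def rec(i: int, rem: list[int], acc: dict[tuple[int, int], int]):
        if len(tables) > bound:
            raise OverflowError("table count exceeds enumeration bound")
        if i == k:
            if all(r == 0 for r in rem):
                tables.append(dict(acc))
            return
        # allocate allele i's remaining copies among (i,i) and (i,j>i)
        def rec_pair(j: int, left: int):
            if len(tables) > bound:
                raise OverflowError("table count exceeds enumeration bound")
            if j == k:
                if left == 0:
                    rec(i + 1, rem, acc)
                return
            cap = min(left, rem[j])
            for c in range(cap + 1):
                if c:
                    acc[(i, j)] = c
                    rem[j] -= c
                rec_pair(j + 1, left - c)
                if c:
                    del acc[(i, j)]
                    rem[j] += c

        for nii in range(rem[i] // 2 + 1):
            if nii:
                acc[(i, i)] = nii
            saved = rem[i]
            rem[i] = 0
            rec_pair(i + 1, saved - 2 * nii)
            rem[i] = saved
            if nii:
                del acc[(i, i)]

    rec(0, list(margins), {})
    return tables


def hwe_exact(
    counts: Mapping[tuple[int, int], int],
    mc_reps: int = 100_000,
    seed: int = 0,
    enumeration_bound: int = 1_000_000,
) -> float:
    """Exact conditional Hardy–Weinberg test.

    The p-value is the total conditional probability (given allele counts)
    of genotype tables no more probable than the observed one. Full
    enumeration when the number of tables is within `enumeration_bound`,
    else Monte-Carlo over random pairings of the allele copies.
    """
    counts = {tuple(sorted(k)): v for k, v in counts.items()}
    n = sum(counts.values())
    if n < 1:
        raise ValueError("need at least one typed individual")
    alleles = sorted({a for pair in counts for a in pair})
    if len(alleles) < 2:
        raise ValueError("monomorphic locus: HWE test undefined")
    aidx = {a: i for i, a in enumerate(alleles)}
    occ = {(aidx[a], aidx[b]): c for (a, b), c in counts.items()}
    margins = [0] * len(alleles)
    for (i, j), c in occ.items():
        margins[i] += c
        margins[j] += c
    lp_obs = _table_logprob(occ, margins, n)
    tol = 1e-9  # ties in log-probability

    try:
        tables = _enumerate_tables(margins, enumeration_bound)
    except OverflowError:
        tables = None

    if tables is not None:
        p = 0.0
        for t in tables:
            lp = _table_logprob(t, margins, n)
            if lp <= lp_obs + tol:
                p += math.exp(lp)
        return min(1.0, p)

    # Monte-Carlo branch: random pairings of the 2n allele copies sample
    # genotype tables from the conditional (Levene) distribution.
    rng = np.random.default_rng(seed)
    copies = np.repeat(np.arange(len(alleles)), margins)
    k = len(alleles)
    hits = 0
    chunk = max(1, min(mc_reps, 200_000 // max(1, n)))
    done = 0
    logn = gammaln(n + 1) + sum(gammaln(m + 1) for m in margins) - gammaln(2 * n + 1)
    while done < mc_reps:
        b = min(chunk, mc_reps - done)
        mat = np.tile(copies, (b, 1))
        mat = rng.permuted(mat, axis=1)
        pairs = mat.reshape(b, n, 2)
        lo = pairs.min(axis=2)
        hi = pairs.max(axis=2)
        code = lo * k + hi
        het = (lo != hi).sum(axis=1)
        occm = np.zeros((b, k * k), dtype=np.int64)
        rows = np.repeat(np.arange(b), n)
        np.add.at(occm, (rows, code.ravel()), 1)
        lp = logn + het * math.log(2.0) - gammaln(occm + 1.0).sum(axis=1)
        hits += int(np.sum(lp <= lp_obs + tol))
        done += b
    return (1 + hits) / (mc_reps + 1)


# ---------------------------------------------------------------------------
# Linkage disequilibrium permutation test
# ---------------------------------------------------------------------------

def _g_statistic(table: np.ndarray) -> float:
    total = table.sum()
    rows = table.sum(axis=1, keepdims=True)
    cols = table.sum(axis=0, keepdims=True)
    expected = rows * cols / total
    mask = table > 0
    return float(2.0 * np.sum(table[mask] * np.log(table[mask] / expected[mask])))


def ld_permutation(
    genotypes: Sequence[StrGenotype],
    locus_a: str,
    locus_b: str,
    reps: int = 999,
    seed: int = 0,
) -> float:
    """Genotypic LD test: G-statistic on the two-locus genotype contingency
    table, null distribution by permuting one locus across individuals."""
    if reps < 100:
        raise ValueError("reps must be >= 100 for a meaningful permutation p-value")
    both = [g for g in genotypes if g.is_typed(locus_a) and g.is_typed(locus_b)]
    if len(both) < 10:
        raise ValueError("need >= 10 individuals typed at both loci")
    ga = [g.pair(locus_a) for g in both]
    gb = [g.pair(locus_b) for g in both]
    cats_a = {c: i for i, c in enumerate(sorted(set(ga)))}
    cats_b = {c: i for i, c in enumerate(sorted(set(gb)))}
    ia = np.array([cats_a[c] for c in ga])
    ib = np.array([cats_b[c] for c in gb])
    na, nb = len(cats_a), len(cats_b)

    def table(b_idx: np.ndarray) -> np.ndarray:
        t = np.zeros((na, nb), dtype=np.int64)
        np.add.at(t, (ia, b_idx), 1)
        return t

    g_obs = _g_statistic(table(ib))
    rng = np.random.default_rng(seed)
    hits = 0
    perm = ib.copy()
    for _ in range(reps):
        rng.shuffle(perm)
        if _g_statistic(table(perm)) >= g_obs - 1e-12:
            hits += 1
    return (1 + hits) / (reps + 1)


# ---------------------------------------------------------------------------
# Genotype accumulation curve
# ---------------------------------------------------------------------------

def _distinct_profiles(sub: list[tuple[tuple[int, int], ...]]) -> int:
    """Distinct multilocus genotypes; a missing locus (0,0) or half call is a
    wildcard that matches anything at that locus (greedy grouping)."""
    def compatible(x, y) -> bool:
        for (a1, b1), (a2, b2) in zip(x, y):
            if 0 in (a1, b1) or 0 in (a2, b2):
                continue
            if (a1, b1) != (a2, b2):
                return False
        return True

    reps: list[tuple] = []
    for prof in sub:
        if not any(compatible(prof, r) for r in reps):
            reps.append(prof)
    return len(reps)


def genotype_accumulation(
    genotypes: Sequence[StrGenotype],
    n_reps: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean and min distinct multilocus genotypes over random locus subsets
    of size m = 1..L, the panel's individualization accumulation curve."""
    if len(genotypes) < 1:
        raise ValueError("need at least one individual")
    loci = genotypes[0].loci
    L = len(loci)
    profiles = [tuple(g.pair(l) for l in loci) for g in genotypes]
    # fast path: no missing data -> set-based distinct count
    has_missing = any(0 in (a, b) for prof in profiles for (a, b) in prof)
    rng = np.random.default_rng(seed)
    rows = []
    for m in range(1, L + 1):
        counts = []
        for _ in range(n_reps):
            idx = rng.choice(L, size=m, replace=False)
            sub = [tuple(prof[i] for i in idx) for prof in profiles]
            if has_missing:
                counts.append(_distinct_profiles(sub))
            else:
                counts.append(len(set(sub)))
        rows.append(
            {
                "n_loci": m,
                "mean_distinct": float(np.mean(counts)),
                "min_distinct": int(np.min(counts)),
            }
        )
    return pd.DataFrame(rows)
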