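"""Per-locus and collection-wide diversity statistics for co-dominant markers.

Implements the classical single-locus summaries (Na, Ne, Ho, He, F), the
Botstein polymorphism information content, the Tessier discriminating power
over single-locus genotype patterns, an EM estimate of null-allele
frequency, and private/rare allele tallies.
"""

from __future__ import annotations

import math
import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeError, GenotypeMatrix


@dataclass
class AlleleFrequencyTable:
    locus_id: str
    freqs: dict[int, float]  # allele length -> relative frequency (> 0)
    n_typed: int  # typed accessions (denominator is 2 * n_typed copies)

    def __post_init__(self) -> None:
        if self.n_typed > 0:
            total = sum(self.freqs.values())
            if abs(total - 1.0) > 1e-12:
                raise ValueError(f"frequencies sum to {total}, expected 1")
            if any(p <= 0 for p in self.freqs.values()):
                raise ValueError("all stored frequencies must be > 0")


@dataclass
class PatternFrequencyTable:
    """Single-locus genotype (unordered pair) pattern frequencies."""

    locus_id: str
    pattern_freqs: dict[tuple[int, int], float]
    n: int  # typed samples

    @property
    def n_patterns(self) -> int:
        return len(self.pattern_freqs)


@dataclass
class LocusDiversitySummary:
    locus_id: str
    na: int
    ne: float
    ho: float
    he: float
    f: float | None  # undefined (None) when He == 0
    pic: float | None = None
    dj: float | None = None
    null_freq: float | None = None


def allele_frequencies(gm: GenotypeMatrix, locus: str) -> AlleleFrequencyTable:
    """Relative allele frequencies at *locus*.

    Both allele copies of every typed call are counted; missing calls are
    excluded from the denominator.
    """
    j = gm.locus_index(locus)
    typed = gm.a1[:, j] != MISSING
    n_typed = int(typed.sum())
    if n_typed == 0:
        return AlleleFrequencyTable(locus, {}, 0)
    copies = np.concatenate([gm.a1[typed, j], gm.a2[typed, j]])
    counts = Counter(int(v) for v in copies)
    total = 2 * n_typed
    return AlleleFrequencyTable(
        locus, {a: c / total for a, c in sorted(counts.items())}, n_typed
    )


def pattern_frequencies(gm: GenotypeMatrix, locus: str) -> PatternFrequencyTable:
    """Frequencies of the distinct single-locus genotype patterns."""
    j = gm.locus_index(locus)
    typed = gm.a1[:, j] != MISSING
    pairs = [
        (int(a), int(b)) for a, b in zip(gm.a1[typed, j], gm.a2[typed, j])
    ]
    n = len(pairs)
    counts = Counter(pairs)
    return PatternFrequencyTable(
        locus, {p: c / n for p, c in sorted(counts.items())}, n
    )


def pic(freqs: AlleleFrequencyTable) -> float:
    """Polymorphism information content (Botstein).

    PIC = 1 - sum_i p_i^2 - sum_i sum_{j>i} 2 p_i^2 p_j^2
    """
    if freqs.n_typed == 0:
        raise GenotypeError(f"locus {freqs.locus_id!r}: no typed calls")
    p = np.array(list(freqs.freqs.values()))
    sum_p2 = float((p**2).sum())
    double = 0.0
    for i in range(len(p)):
        for j in range(i + 1, len(p)):
            double += 2.0 * p[i] ** 2 * p[j] ** 2
    return 1.0 - sum_p2 - double


def discriminating_power(patterns: PatternFrequencyTable) -> float:
    """Probability that two random samples show distinct single-locus
    genotype patterns (Tessier), with finite-sample correction:

    Dj = 1 - sum_i p_i (N p_i - 1) / (N - 1)
    """
    n = patterns.n
    if n < 2:
        raise GenotypeError(
            f"locus {patterns.locus_id!r}: need >= 2 typed samples for Dj"
        )
    c = sum(p * (n * p - 1.0) / (n - 1.0) for p in patterns.pattern_freqs.values())
    return 1.0 - c


def locus_summary(
    gm: GenotypeMatrix, locus: str, unbiased: bool = False
) -> LocusDiversitySummary:
    """Na, Ne, Ho, He and F at a locus.

    He defaults to the biased estimator 1 - sum p^2; ``unbiased=True``
    applies the 2N/(2N-1) small-sample correction.  F = (He - Ho)/He is
    None when He == 0 (monomorphic locus).
    """
    ft = allele_frequencies(gm, locus)
    if ft.n_typed == 0:
        raise GenotypeError(f"locus {locus!r}: no typed calls")
    p = np.array(list(ft.freqs.values()))
    na = len(p)
    sum_p2 = float((p**2).sum())
    ne = 1.0 / sum_p2
    he = 1.0 - sum_p2
    if unbiased and ft.n_typed > 0:
        ncopies = 2 * ft.n_typed
        if ncopies > 1:
            he *= ncopies / (ncopies - 1)
    j = gm.locus_index(locus)
    typed = gm.a1[:, j] != MISSING
    het = (gm.a1[typed, j] != gm.a2[typed, j]).sum()
    ho = float(het) / ft.n_typed
    f = None if he == 0 else (he - ho) / he
    return LocusDiversitySummary(locus, na, ne, ho, he, f)


def null_allele_frequency(
    gm: GenotypeMatrix,
    locus: str,
    include_missing: bool = True,
    tol: float = 1e-6,
    max_iter: int = 1000,
    min_typed: int = 10,
) -> float | None:
    """Maximum-likelihood null-allele frequency via expectation-maximization.

    The null is treated as one extra unobservable allele with frequency r:
    an observed homozygote a/a may be a true a/a or an a/null heterozygote.
    Phase 1 excludes putative null homozygotes (missing calls) from the
    likelihood; phase 2 (``include_missing``, default on) re-includes
    missing calls as candidate null/null genotypes.  Returns r in [0, 1);
    r is ~0 when there is no homozygote excess.  Returns None with a warning
    below *min_typed* typed calls.
    """
    j = gm.locus_index(locus)
    typed = gm.a1[:, j] != MISSING
    n_typed = int(typed.sum())
    if n_typed < min_typed:
        warnings.warn(
            f"locus {locus!r}: only {n_typed} typed calls (< {min_typed}); "
            "null-allele frequency undefined",
            stacklevel=2,
        )
        return None
    a1t, a2t = gm.a1[typed, j], gm.a2[typed, j]
    hom = Counter(int(a) for a, b in zip(a1t, a2t) if a == b)
    het_copies = Counter()
    for a, b in zip(a1t, a2t):
        if a != b:
            het_copies[int(a)] += 1
            het_copies[int(b)] += 1
    n_missing = int((~typed).sum())
    alleles = sorted(set(hom) | set(het_copies))
    idx = {a: k for k, a in enumerate(alleles)}
    hom_n = np.zeros(len(alleles))
    for a, c in hom.items():
        hom_n[idx[a]] = c
    het_n = np.zeros(len(alleles))
    for a, c in het_copies.items():
        het_n[idx[a]] = c

    def em(with_missing: bool, r0: float) -> float:
        r = r0
        # start from observed copy shares scaled to (1 - r)
        p = (het_n + 2 * hom_n) / (het_n + 2 * hom_n).sum() * (1 - r)
        for _ in range(max_iter):
            # posterior that an observed a/a homozygote is truly a/a
            w = np.where(p + 2 * r > 0, p / np.maximum(p + 2 * r, 1e-300), 1.0)
            exp_a = het_n + hom_n * (1.0 + w)
            exp_null = float((hom_n * (1.0 - w)).sum())
            n_calls = n_typed
            if with_missing:
                exp_null += 2.0 * n_missing
                n_calls += n_missing
            total = 2.0 * n_calls
            p_new = exp_a / total
            r_new = exp_null / total
            if abs(r_new - r) < tol:
                r, p = r_new, p_new
                break
            r, p = r_new, p_new
        return float(min(max(r, 0.0), 1.0 - 1e-12))

    r1 = em(False, 0.05)  # phase 1: null homozygotes not considered
    if include_missing and n_missing > 0:
        return em(True, r1)  # phase 2: missing re-included as null/null
    return r1


@dataclass
class PrivateRareResult:
    private: dict[str, list[tuple[str, int]]]  # group -> [(locus, allele)]
    rare: list[tuple[str, int]]  # whole-collection frequency < 0.05


def private_and_rare_alleles(
    gm: GenotypeMatrix,
    grouping: Mapping[str, str],
    rare_threshold: float = 0.05,
) -> PrivateRareResult:
    """Private alleles per group and globally rare alleles.

    An allele is private to group g iff observed in g and in no other group;
    rare iff its whole-collection frequency is strictly below
    *rare_threshold*.  Every accession must be labeled (an explicit
    "admixed" label counts as a group).
    """
    for acc in grouping:
        if acc not in gm.accession_ids:
            raise GenotypeError(f"grouping names unknown accession {acc!r}")
    missing_lbl = [a for a in gm.accession_ids if a not in grouping]
    if missing_lbl:
        raise GenotypeError(
            f"accession {missing_lbl[0]!r} has no group label"
        )
    groups = sorted(set(grouping.values()))
    counts: dict[str, Counter] = {g: Counter() for g in groups}
    for i, acc in enumerate(gm.accession_ids):
        g = grouping[acc]
        for j, locus in enumerate(gm.locus_ids):
            if gm.a1[i, j] != MISSING:
                counts[g][(locus, int(gm.a1[i, j]))] += 1
                counts[g][(locus, int(gm.a2[i, j]))] += 1
    private: dict[str, list[tuple[str, int]]] = {g: [] for g in groups}
    all_keys = set().union(*(set(c) for c in counts.values()))
    for key in sorted(all_keys):
        holders = [g for g in groups if counts[g][key] > 0]
        if len(holders) == 1:
            private[holders[0]].append(key)
    rare = []
    for locus in gm.locus_ids:
        ft = allele_frequencies(gm, locus)
        for a, pfreq in ft.freqs.items():
            if pfreq < rare_threshold:
                rare.append((locus, a))
    return PrivateRareResult(private, rare)


def full_locus_summary(
    gm: GenotypeMatrix, locus: str, unbiased: bool = False
) -> LocusDiversitySummary:
    """Locus summary including PIC, Dj and null-allele frequency."""
    s = locus_summary(gm, locus, unbiased=unbiased)
    s.pic = pic(allele_frequencies(gm, locus))
    pt = pattern_frequencies(gm, locus)
    s.dj = discriminating_power(pt) if pt.n >= 2 else None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        s.null_freq = null_allele_frequency(gm, locus)
    return s


@dataclass
class CollectionSummary:
    per_locus: list[LocusDiversitySummary]
    total_na: int
    total_ne: float
    means: dict[str, float]
    ses: dict[str, float]  # standard errors, sd / sqrt(L)


def collection_summary(
    gm: GenotypeMatrix, unbiased: bool = False, full: bool = True
) -> CollectionSummary:
    """Totals (Na, Ne summed over loci) and cross-locus means with standard
    errors.  F is excluded from means at loci where it is undefined."""
    if gm.n_loci < 1:
        raise GenotypeError("need at least one locus")
    make = full_locus_summary if full else locus_summary
    per_locus = [make(gm, l, unbiased=unbiased) for l in gm.locus_ids]
    stats: dict[str, list[float]] = {}
    for name in ("na", "ne", "ho", "he", "f", "pic", "dj"):
        vals = [getattr(s, name) for s in per_locus]
        stats[name] = [v for v in vals if v is not None]
    means, ses = {}, {}
    for name, vals in stats.items():
        if not vals:
            continue
        arr = np.array(vals, dtype=float)
        means[name] = float(arr.mean())
        ses[name] = (
            float(arr.std(ddof=1) / math.sqrt(len(arr))) if len(arr) > 1 else 0.0
        )
    return CollectionSummary(
        per_locus=per_locus,
        total_na=int(sum(s.na for s in per_locus)),
        total_ne=float(sum(s.ne for s in per_locus)),
        means=means,
        ses=ses,
    )


def locus_table(gm: GenotypeMatrix, unbiased: bool = False) -> pd.DataFrame:
    """Per-locus report with columns locus, Na, Ne, Ho, He, PIC, Dj, r."""
    rows = []
    for s in collection_summary(gm, unbiased=unbiased).per_locus:
        rows.append(
            {
                "locus": s.locus_id,
                "Na": s.na,
                "Ne": s.ne,
                "Ho": s.ho,
                "He": s.he,
                "F": s.f,
                "PIC": s.pic,
                "Dj": s.dj,
                "r": s.null_freq,
            }
        )
    return pd.DataFrame(rows)
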