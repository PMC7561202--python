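"""Synthetic germplasm generator with ground truth.

Emulates the structure of a clonally propagated, multi-pool germplasm
collection genotyped at SSR loci: ancestral gene pools in Hardy-Weinberg
equilibrium at unlinked loci, Dirichlet-admixed hybrids, exact-profile
clones registered under the same name (duplicates) or new names
(synonyms), per-locus null alleles applied at the allele-copy level
(null/x renders as the x/x homozygote, null/null as a missing call), and
sporadic independent missingness.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .genotypes import (
    MISSING,
    GenotypeError,
    GenotypeMatrix,
    ReferenceProfile,
    ReferenceProfilePanel,
    STANDARD_FINGERPRINT_LOCI,
)


@dataclass
class SimulationConfig:
    n_pools: int = 3
    n_loci: int = 17
    alleles_per_locus: tuple[int, int] = (10, 24)
    divergence: float = 0.5  # Dirichlet scale; smaller = more divergent pools
    n_pure: int | Sequence[int] = 100  # per pool
    n_admixed: int = 100
    admix_alpha: float = 0.5
    n_duplicate_pairs: int = 0
    n_synonym_groups: int = 0
    missing_rate: float = 0.02
    null_rate: float | Sequence[float] = 0.0  # per locus
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.seed is None:
            raise GenotypeError("seed is mandatory")
        if self.n_pools < 1 or self.n_loci < 1:
            raise GenotypeError("n_pools and n_loci must be >= 1")
        lo, hi = self.alleles_per_locus
        if lo < 1 or hi < lo:
            raise GenotypeError("invalid alleles_per_locus range")
        if not (0 <= self.missing_rate < 1):
            raise GenotypeError("missing_rate must be in [0, 1)")
        rates = self.null_rates
        if any(not (0 <= r < 1) for r in rates):
            raise GenotypeError("null rates must be in [0, 1)")
        for c in (self.n_admixed, self.n_duplicate_pairs, self.n_synonym_groups):
            if c < 0:
                raise GenotypeError("counts must be >= 0")

    @property
    def n_pure_per_pool(self) -> list[int]:
        if isinstance(self.n_pure, int):
            return [self.n_pure] * self.n_pools
        vals = list(self.n_pure)
        if len(vals) != self.n_pools:
            raise GenotypeError("n_pure sequence length must equal n_pools")
        return vals

    @property
    def null_rates(self) -> list[float]:
        if isinstance(self.null_rate, (int, float)):
            return [float(self.null_rate)] * self.n_loci
        vals = [float(v) for v in self.null_rate]
        if len(vals) != self.n_loci:
            raise GenotypeError("null_rate sequence length must equal n_loci")
        return vals


@dataclass
class SimulationTruth:
    ancestry: dict[str, np.ndarray]  # accession -> pool proportions (sum 1)
    clone_groups: dict[str, list[str]]  # source accession -> clone copies
    null_rates: list[float]  # per locus
    pool_freqs: list[dict[str, dict[int, float]]]  # pool -> locus -> freqs
    names: dict[str, str]  # accession -> declared name


def _allele_ladder(rng: np.random.Generator, n_alleles: int) -> list[int]:
    """Arithmetic bp progression with a locus-specific 2-4 bp step."""
    start = int(rng.integers(80, 260))
    step = int(rng.integers(2, 5))
    return [start + step * k for k in range(n_alleles)]


def simulate_germplasm(
    config: SimulationConfig,
) -> tuple[GenotypeMatrix, SimulationTruth]:
    """Draw a germplasm collection and its ground truth.

    Per locus, base frequencies are symmetric-Dirichlet over the allele
    set and each pool's frequencies are Dirichlet with concentration
    ``divergence * n_alleles * base`` (so smaller divergence means more
    divergent pools while retaining allelic richness).  Pure individuals
    draw both copies i.i.d. from their pool; admixed individuals draw each
    copy from a pool sampled by their Dirichlet ancestry.  Reproducible
    given the seed.
    """
    rng = np.random.default_rng(config.seed)
    P = config.n_pools
    L = config.n_loci
    locus_ids = [f"L{j + 1:02d}" for j in range(L)]
    lo, hi = config.alleles_per_locus
    ladders: list[list[int]] = []
    pool_freqs_arr: list[np.ndarray] = []  # per locus: P x A
    for j in range(L):
        A = int(rng.integers(lo, hi + 1))
        ladders.append(_allele_ladder(rng, A))
        base = rng.dirichlet(np.ones(A))
        conc = np.maximum(config.divergence * A * base, 1e-6)
        pool_freqs_arr.append(
            np.stack([rng.dirichlet(conc) for _ in range(P)])
        )

    accession_ids: list[str] = []
    names: dict[str, str] = {}
    ancestry: dict[str, np.ndarray] = {}
    calls: list[list[tuple[int, int] | None]] = []
    counter = 0

    def draw_individual(theta: np.ndarray) -> list[tuple[int, int]]:
        row = []
        for j in range(L):
            pair = []
            for _ in range(2):
                pool = int(rng.choice(P, p=theta))
                a = int(rng.choice(len(ladders[j]), p=pool_freqs_arr[j][pool]))
                pair.append(ladders[j][a])
            row.append((min(pair), max(pair)))
        return row

    for pool, n_pure in enumerate(config.n_pure_per_pool):
        theta = np.zeros(P)
        theta[pool] = 1.0
        for _ in range(n_pure):
            counter += 1
            acc = f"ACC{counter:04d}"
            accession_ids.append(acc)
            names[acc] = f"Cultivar {counter:04d}"
            ancestry[acc] = theta.copy()
            calls.append(draw_individual(theta))
    for _ in range(config.n_admixed):
        counter += 1
        acc = f"ACC{counter:04d}"
        theta = rng.dirichlet(np.full(P, config.admix_alpha))
        accession_ids.append(acc)
        names[acc] = f"Hybrid {counter:04d}"
        ancestry[acc] = theta
        calls.append(draw_individual(theta))

    # null alleles at the copy level, then independent missingness
    rates = config.null_rates
    final_calls: list[list[tuple[int, int] | None]] = []
    for row in calls:
        out_row: list[tuple[int, int] | None] = []
        for j, call in enumerate(row):
            a, b = call
            null_a = rng.random() < rates[j]
            null_b = rng.random() < rates[j]
            if null_a and null_b:
                out_row.append(None)  # null homozygote: no amplification
            elif null_a:
                out_row.append((b, b))
            elif null_b:
                out_row.append((a, a))
            else:
                out_row.append((a, b))
            if out_row[-1] is not None and rng.random() < config.missing_rate:
                out_row[-1] = None
        final_calls.append(out_row)

    # clones copy the final observed profile (same genotype, same null
    # effects), so they are exact profile copies by construction: same
    # name for duplicates, a fresh name for synonyms
    clone_groups: dict[str, list[str]] = {}
    n_base = len(accession_ids)
    n_clone_sources = config.n_duplicate_pairs + config.n_synonym_groups
    if n_clone_sources > n_base:
        raise GenotypeError("more clone groups requested than base accessions")
    sources = rng.choice(n_base, size=n_clone_sources, replace=False)
    for s_idx, src_i in enumerate(sources):
        src = accession_ids[src_i]
        counter += 1
        acc = f"ACC{counter:04d}"
        accession_ids.append(acc)
        ancestry[acc] = ancestry[src].copy()
        final_calls.append(list(final_calls[src_i]))
        if s_idx < config.n_duplicate_pairs:
            names[acc] = names[src]  # duplicate: same declared name
        else:
            names[acc] = f"Synonym {counter:04d}"  # synonym: new name
        clone_groups.setdefault(src, []).append(acc)

    metadata = {acc: {"name": names[acc]} for acc in accession_ids}
    gm = GenotypeMatrix.from_calls(accession_ids, locus_ids, final_calls, metadata)
    pool_freqs = [
        {
            locus_ids[j]: {
                ladders[j][a]: float(pool_freqs_arr[j][p][a])
                for a in range(len(ladders[j]))
            }
            for j in range(L)
        }
        for p in range(P)
    ]
    truth = SimulationTruth(
        ancestry=ancestry,
        clone_groups=clone_groups,
        null_rates=rates,
        pool_freqs=pool_freqs,
        names=names,
    )
    return gm, truth


# -- pinned fixtures -------------------------------------------------------


@dataclass
class CloneBankFixture:
    gm: GenotypeMatrix
    panel: ReferenceProfilePanel
    manifest: dict  # expected identity-report content


def _tiny6() -> GenotypeMatrix:
    """Six accessions, two loci, constructed so that accessions T1 and T4
    jointly carry every allele (brute-force core-selection oracle)."""
    calls = [
        [(100, 102), (200, 204)],  # T1
        [(100, 100), (200, 200)],  # T2
        [(102, 102), (204, 204)],  # T3
        [(104, 106), (202, 206)],  # T4
        [(100, 104), (200, 202)],  # T5
        [(102, 106), (204, 206)],  # T6
    ]
    return GenotypeMatrix.from_calls(
        [f"T{i}" for i in range(1, 7)], ["La", "Lb"], calls
    )


def _threepools() -> tuple[GenotypeMatrix, SimulationTruth]:
    config = SimulationConfig(
        n_pools=3,
        n_loci=17,
        alleles_per_locus=(8, 14),
        divergence=0.08,
        n_pure=30,
        n_admixed=0,
        missing_rate=0.0,
        null_rate=0.0,
        seed=20240917,
    )
    return simulate_germplasm(config)


def _clonebank() -> CloneBankFixture:
    """Accessions with a matching reference panel exercising every identity
    category: validated, misnamed, unknown, unreported, duplicates and
    synonyms.  Fully deterministic."""
    rng = np.random.default_rng(77)
    loci = list(STANDARD_FINGERPRINT_LOCI)
    ladders = {l: _allele_ladder(rng, 12) for l in loci}

    def random_profile() -> dict[str, tuple[int, int]]:
        prof = {}
        for l in loci:
            a, b = rng.choice(ladders[l], size=2, replace=True)
            prof[l] = (int(min(a, b)), int(max(a, b)))
        return prof

    ref_names = [f"Variety {chr(65 + i)}" for i in range(8)]  # A..H
    profiles = {}
    seen = set()
    for name in ref_names:
        while True:
            prof = random_profile()
            key = tuple(sorted(prof.items()))
            if key not in seen:
                seen.add(key)
                profiles[name] = prof
                break
    panel = ReferenceProfilePanel(
        loci,
        [ReferenceProfile(nm, dict(profiles[nm]), "local") for nm in ref_names],
    )

    rows: list[tuple[str, str, dict[str, tuple[int, int]]]] = []
    # validated: declared name matches its reference profile
    rows.append(("CB01", "Variety A", profiles["Variety A"]))
    rows.append(("CB02", "Variety B", profiles["Variety B"]))
    # misnamed: profile of C declared under another name
    rows.append(("CB03", "Variety D", profiles["Variety C"]))
    # unknown: name in the panel but profile matches nothing
    unk = random_profile()
    while tuple(sorted(unk.items())) in seen:
        unk = random_profile()
    seen.add(tuple(sorted(unk.items())))
    rows.append(("CB04", "Variety E", unk))
    # unreported: neither name nor profile known
    unrep = random_profile()
    while tuple(sorted(unrep.items())) in seen:
        unrep = random_profile()
    seen.add(tuple(sorted(unrep.items())))
    rows.append(("CB05", "Local Selection 1", unrep))
    # duplicates: same name, same profile as CB01
    rows.append(("CB06", "Variety A", profiles["Variety A"]))
    # synonyms: same profile as CB02, different name
    rows.append(("CB07", "Old Name 7", profiles["Variety B"]))
    # an unreported pair forming a synonym group of its own
    unrep2 = random_profile()
    while tuple(sorted(unrep2.items())) in seen:
        unrep2 = random_profile()
    rows.append(("CB08", "Local Selection 2", unrep2))
    rows.append(("CB09", "Local Selection 3", unrep2))

    accession_ids = [r[0] for r in rows]
    metadata = {r[0]: {"name": r[1]} for r in rows}
    calls = [[r[2][l] for l in loci] for r in rows]
    gm = GenotypeMatrix.from_calls(accession_ids, loci, calls, metadata)
    manifest = {
        "validated": [["CB01", "Variety A"], ["CB02", "Variety B"],
                      ["CB06", "Variety A"]],
        "misnamed": [["CB03", "Variety C"], ["CB07", "Variety B"]],
        "unknown": ["CB04"],
        "unreported": ["CB05", "CB08", "CB09"],
        "duplicate_groups": [["CB01", "CB06"]],
        "synonym_groups": [["CB02", "CB07"], ["CB08", "CB09"]],
        "n_unique_genotypes": 6,
    }
    return CloneBankFixture(gm, panel, manifest)


def fixture_library() -> dict[str, object]:
    """Named deterministic datasets: ``tiny6`` (brute-force core tests),
    ``threepools`` (n=90, strong divergence), ``clonebank`` (identity
    categories with matching panel and manifest).  Byte-identical across
    calls."""
    gm3, truth3 = _threepools()
    return {
        "tiny6": _tiny6(),
        "threepools": (gm3, truth3),
        "clonebank": _clonebank(),
    }
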