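"""Fingerprint-based identity resolution.

Groups accessions with identical multilocus profiles into duplicate groups
(same declared name) and synonym groups (different names), and validates
declared names against a local reference fingerprint panel (validated /
misnamed / unreported / unknown).

Profile identity is exact equality at every compared locus -- a typed call
never matches a missing one, and there is no +-1 bp fuzzy matching, which
keeps equality an equivalence relation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .genotypes import (
    MISSING,
    GenotypeError,
    GenotypeMatrix,
    ReferenceProfilePanel,
    STANDARD_FINGERPRINT_LOCI,
    normalize_name,
)

ProfileKey = tuple[tuple[str, tuple[int, int] | None], ...]


class PanelInconsistencyError(GenotypeError):
    """One profile matches panel entries carrying different prime names."""


def profile_key(
    gm: GenotypeMatrix, accession: str, loci: Sequence[str] | None = None
) -> ProfileKey:
    """Canonical serialization of an accession's calls over a locus subset.

    Locus-sorted and allele-sorted, with missing loci recorded explicitly,
    so the key is invariant to input column order and within-call allele
    order.
    """
    loci = list(loci) if loci is not None else list(gm.locus_ids)
    i = gm.accession_index(accession)
    parts: list[tuple[str, tuple[int, int] | None]] = []
    for locus in sorted(loci):
        j = gm.locus_index(locus)
        if gm.a1[i, j] == MISSING:
            parts.append((locus, None))
        else:
            parts.append((locus, (int(gm.a1[i, j]), int(gm.a2[i, j]))))
    return tuple(parts)


@dataclass
class DedupResult:
    duplicate_groups: list[list[str]]  # identical profile, one shared name
    synonym_groups: list[list[str]]  # identical profile, >= 2 distinct names
    n_unique_genotypes: int
    excluded: list[str] = field(default_factory=list)  # below min typed loci


def find_duplicates_and_synonyms(
    gm: GenotypeMatrix,
    loci: Sequence[str] | None = None,
    min_typed: int | None = None,
) -> DedupResult:
    """Group accessions by identical profile over *loci* (default: all).

    Within a profile group, identical normalized declared names make a
    duplicate group, differing names a synonym group.  Accessions typed at
    fewer than *min_typed* of the compared loci (default: all of them) are
    excluded with a warning.  Also reports the number of distinct multilocus
    genotypes among the included accessions.
    """
    loci = list(loci) if loci is not None else list(gm.locus_ids)
    if min_typed is None:
        min_typed = len(loci)
    groups: dict[ProfileKey, list[str]] = {}
    excluded: list[str] = []
    for acc in gm.accession_ids:
        key = profile_key(gm, acc, loci)
        n_typed = sum(1 for _, call in key if call is not None)
        if n_typed < min_typed:
            excluded.append(acc)
            continue
        groups.setdefault(key, []).append(acc)
    if excluded:
        warnings.warn(
            f"{len(excluded)} accession(s) typed at fewer than {min_typed} "
            f"of the compared loci were excluded: {excluded[:5]}...",
            stacklevel=2,
        )
    duplicates: list[list[str]] = []
    synonyms: list[list[str]] = []
    # missing calls (None) sort before any typed pair
    sort_key = lambda key: [(l, c if c is not None else (0, 0)) for l, c in key]
    for key in sorted(groups, key=sort_key):
        members = groups[key]
        if len(members) < 2:
            continue
        names = {normalize_name(gm.declared_name(a)) for a in members}
        (duplicates if len(names) == 1 else synonyms).append(sorted(members))
    return DedupResult(
        duplicate_groups=duplicates,
        synonym_groups=synonyms,
        n_unique_genotypes=len(groups),
        excluded=excluded,
    )


@dataclass
class IdentityReport:
    duplicate_groups: list[list[str]]
    synonym_groups: list[list[str]]
    validated: list[tuple[str, str]]  # (accession, prime name)
    misnamed: list[tuple[str, str]]  # (accession, matched prime name)
    unreported: list[str]  # profile matches no reference
    unknown: list[str]  # declared name known to panel but profile differs
    excluded: list[str]  # not comparable (missing panel loci)
    n_unique_genotypes: int | None = None

    def to_dict(self) -> dict:
        return {
            "duplicate_groups": self.duplicate_groups,
            "synonym_groups": self.synonym_groups,
            "validated": [list(t) for t in self.validated],
            "misnamed": [list(t) for t in self.misnamed],
            "unreported": self.unreported,
            "unknown": self.unknown,
            "excluded": self.excluded,
            "n_unique_genotypes": self.n_unique_genotypes,
        }


def match_to_references(
    gm: GenotypeMatrix,
    panel: ReferenceProfilePanel,
    declared_names: Mapping[str, str] | None = None,
    mode: str = "strict",
    min_shared: int = 6,
) -> IdentityReport:
    """Compare accession fingerprints with a reference panel.

    An exact profile match over the panel loci to an entry whose prime name
    equals the declared name (after normalization) is *validated*; an exact
    match to a different prime name is *misnamed*; no match with a declared
    name present in the panel is *unknown*; no match otherwise is
    *unreported*.  ``mode="strict"`` (default) requires all panel loci
    typed; ``mode="lenient"`` compares over shared typed loci with at least
    *min_shared* of them.  A profile matching two entries with different
    prime names raises :class:`PanelInconsistencyError`.
    """
    if mode not in ("strict", "lenient"):
        raise ValueError(f"unknown mode {mode!r}")
    missing_loci = [l for l in panel.loci if l not in gm.locus_ids]
    if missing_loci:
        raise GenotypeError(
            f"panel loci not in genotype matrix: {missing_loci}"
        )
    names = dict(declared_names) if declared_names is not None else {
        acc: gm.declared_name(acc) for acc in gm.accession_ids
    }
    panel_names_norm = {normalize_name(e.prime_name) for e in panel.entries}
    validated: list[tuple[str, str]] = []
    misnamed: list[tuple[str, str]] = []
    unreported: list[str] = []
    unknown: list[str] = []
    excluded: list[str] = []
    for acc in gm.accession_ids:
        i = gm.accession_index(acc)
        calls: dict[str, tuple[int, int] | None] = {}
        for locus in panel.loci:
            j = gm.locus_index(locus)
            calls[locus] = (
                None
                if gm.a1[i, j] == MISSING
                else (int(gm.a1[i, j]), int(gm.a2[i, j]))
            )
        typed_loci = [l for l, c in calls.items() if c is not None]
        if mode == "strict" and len(typed_loci) < len(panel.loci):
            excluded.append(acc)
            continue
        if mode == "lenient" and len(typed_loci) < min_shared:
            excluded.append(acc)
            continue
        compare = panel.loci if mode == "strict" else typed_loci
        matches = [
            e
            for e in panel.entries
            if all(calls[l] == e.profile[l] for l in compare if calls[l] is not None)
            and all(calls[l] is not None for l in compare)
        ]
        match_names = {normalize_name(e.prime_name) for e in matches}
        if len(match_names) > 1:
            raise PanelInconsistencyError(
                f"accession {acc!r} matches panel entries with different "
                f"prime names: {sorted(e.prime_name for e in matches)}"
            )
        declared = normalize_name(names.get(acc, acc))
        if matches:
            prime = matches[0].prime_name
            if normalize_name(prime) == declared:
                validated.append((acc, prime))
            else:
                misnamed.append((acc, prime))
        else:
            if declared in panel_names_norm:
                unknown.append(acc)
            else:
                unreported.append(acc)
    dedup = find_duplicates_and_synonyms(gm)
    return IdentityReport(
        duplicate_groups=dedup.duplicate_groups,
        synonym_groups=dedup.synonym_groups,
        validated=validated,
        misnamed=misnamed,
        unreported=unreported,
        unknown=unknown,
        excluded=excluded,
        n_unique_genotypes=dedup.n_unique_genotypes,
    )


def apply_relabeling(
    gm: GenotypeMatrix, corrections: Mapping[str, str]
) -> GenotypeMatrix:
    """Return a copy with declared names (metadata 'name') replaced for the
    corrected accessions -- e.g. the misnamed list of an identity report."""
    meta = {acc: dict(m) for acc, m in gm.metadata.items()}
    for acc, prime in corrections.items():
        if acc not in gm.accession_ids:
            raise GenotypeError(f"correction names unknown accession {acc!r}")
        meta.setdefault(acc, {})["name"] = prime
    return GenotypeMatrix(gm.accession_ids, gm.locus_ids, gm.a1, gm.a2, meta)
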