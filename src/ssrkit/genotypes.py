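"""Genotype data model and text I/O for multi-allelic co-dominant markers.

The central object is :class:`GenotypeMatrix`: accessions x loci, each cell
an unordered diploid pair of integer allele lengths (base pairs) or missing.
Alleles are discrete integers -- no fuzzy/binned matching -- so profile
equality stays transitive.
"""

from __future__ import annotations

import csv
import io
import re
import unicodedata
import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

MISSING = -1

#: Locus subset conventionally used for variety fingerprint exchange.
STANDARD_FINGERPRINT_LOCI = (
    "VVS2", "VVMD5", "VVMD7", "VVMD25", "VVMD27", "VrZAG62", "VrZAG79",
)

META_PREFIX = "meta:"


class GenotypeError(ValueError):
    """Invalid genotype data or operation."""


class GenotypeParseError(GenotypeError):
    """Malformed input table."""


class StandardizationError(GenotypeError):
    """Allele-size standardization failed a consistency check."""


def normalize_name(name: str) -> str:
    """Canonicalize an accession/variety name for comparison.

    Case-folds, strips accents and punctuation, collapses whitespace.
    Distinct words are never merged.
    """
    s = unicodedata.normalize("NFKD", name)
    s = "".join(c for c in s if not unicodedata.combining(c))
    s = re.sub(r"[^\w\s]", " ", s.casefold())
    return re.sub(r"\s+", " ", s).strip()


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen = Counter(ids)
    dups = [k for k, v in seen.items() if v > 1]
    if dups:
        raise GenotypeError(f"duplicate {what} ID: {dups[0]!r}")


@dataclass
class GenotypeMatrix:
    """Accessions x loci table of unordered diploid allele-size pairs.

    Parameters
    ----------
    accession_ids, locus_ids:
        Unique row / column labels.
    a1, a2:
        Integer arrays of shape (n_accessions, n_loci) holding the smaller
        and larger allele of each call; both equal to :data:`MISSING` (-1)
        for a missing call.  Homozygotes store the same value twice.
    metadata:
        Optional per-accession key -> text map (e.g. declared cultivar name
        under key ``"name"``, species, origin).
    """

    accession_ids: list[str]
    locus_ids: list[str]
    a1: np.ndarray
    a2: np.ndarray
    metadata: dict[str, dict[str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.accession_ids = list(self.accession_ids)
        self.locus_ids = list(self.locus_ids)
        _check_unique(self.accession_ids, "accession")
        _check_unique(self.locus_ids, "locus")
        self.a1 = np.asarray(self.a1, dtype=np.int64).copy()
        self.a2 = np.asarray(self.a2, dtype=np.int64).copy()
        shape = (len(self.accession_ids), len(self.locus_ids))
        if self.a1.shape != shape or self.a2.shape != shape:
            raise GenotypeError(
                f"allele arrays have shape {self.a1.shape}, expected {shape}"
            )
        # normalize pair order: min first
        swap = self.a1 > self.a2
        if swap.any():
            lo = np.where(swap, self.a2, self.a1)
            hi = np.where(swap, self.a1, self.a2)
            self.a1, self.a2 = lo, hi
        m1 = self.a1 == MISSING
        m2 = self.a2 == MISSING
        if (m1 != m2).any():
            i, j = np.argwhere(m1 != m2)[0]
            raise GenotypeError(
                f"half-call at accession {self.accession_ids[i]!r}, "
                f"locus {self.locus_ids[j]!r}: both alleles must be typed or missing"
            )
        typed = ~m1
        if (self.a1[typed] <= 0).any() or (self.a2[typed] <= 0).any():
            raise GenotypeError("allele lengths must be positive integers")
        for acc in self.metadata:
            if acc not in set(self.accession_ids):
                raise GenotypeError(f"metadata for unknown accession {acc!r}")

    # -- basic accessors ---------------------------------------------------

    @property
    def n_accessions(self) -> int:
        return len(self.accession_ids)

    @property
    def n_loci(self) -> int:
        return len(self.locus_ids)

    @property
    def typed_mask(self) -> np.ndarray:
        """Boolean (n, L): True where the call is typed."""
        return self.a1 != MISSING

    def accession_index(self, accession: str) -> int:
        try:
            return self.accession_ids.index(accession)
        except ValueError:
            raise GenotypeError(f"unknown accession {accession!r}") from None

    def locus_index(self, locus: str) -> int:
        try:
            return self.locus_ids.index(locus)
        except ValueError:
            raise GenotypeError(f"unknown locus {locus!r}") from None

    def call(self, accession: str, locus: str) -> tuple[int, int] | None:
        i = self.accession_index(accession)
        j = self.locus_index(locus)
        if self.a1[i, j] == MISSING:
            return None
        return int(self.a1[i, j]), int(self.a2[i, j])

    def alleles_at(self, locus: str) -> list[int]:
        """Sorted distinct allele lengths observed at *locus*."""
        j = self.locus_index(locus)
        typed = self.a1[:, j] != MISSING
        vals = np.concatenate([self.a1[typed, j], self.a2[typed, j]])
        return sorted(int(v) for v in np.unique(vals))

    def declared_name(self, accession: str) -> str:
        """Declared cultivar name (metadata key 'name'), defaulting to the ID."""
        return self.metadata.get(accession, {}).get("name", accession)

    def subset(
        self,
        accessions: Sequence[str] | None = None,
        loci: Sequence[str] | None = None,
    ) -> "GenotypeMatrix":
        acc = list(accessions) if accessions is not None else self.accession_ids
        loc = list(loci) if loci is not None else self.locus_ids
        ai = [self.accession_index(a) for a in acc]
        lj = [self.locus_index(l) for l in loc]
        meta = {a: dict(self.metadata[a]) for a in acc if a in self.metadata}
        return GenotypeMatrix(
            acc, loc, self.a1[np.ix_(ai, lj)], self.a2[np.ix_(ai, lj)], meta
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.accession_ids == other.accession_ids
            and self.locus_ids == other.locus_ids
            and np.array_equal(self.a1, other.a1)
            and np.array_equal(self.a2, other.a2)
            and self.metadata == other.metadata
        )

    @classmethod
    def from_calls(
        cls,
        accession_ids: Sequence[str],
        locus_ids: Sequence[str],
        calls: Sequence[Sequence[tuple[int, int] | None]],
        metadata: Mapping[str, Mapping[str, str]] | None = None,
    ) -> "GenotypeMatrix":
        """Build a matrix from a nested list of calls (None = missing)."""
        n, L = len(accession_ids), len(locus_ids)
        a1 = np.full((n, L), MISSING, dtype=np.int64)
        a2 = np.full((n, L), MISSING, dtype=np.int64)
        for i, row in enumerate(calls):
            for j, c in enumerate(row):
                if c is not None:
                    a1[i, j], a2[i, j] = c
        meta = {k: dict(v) for k, v in (metadata or {}).items()}
        return cls(list(accession_ids), list(locus_ids), a1, a2, meta)


# -- reference panel -------------------------------------------------------


@dataclass
class ReferenceProfile:
    prime_name: str
    profile: dict[str, tuple[int, int]]
    source: str = ""


@dataclass
class ReferenceProfilePanel:
    """Named fingerprints over a declared locus subset, used for
    trueness-to-type validation against local reference data."""

    loci: list[str]
    entries: list[ReferenceProfile]

    def __post_init__(self) -> None:
        self.loci = list(self.loci)
        _check_unique(self.loci, "panel locus")
        for e in self.entries:
            if not e.prime_name:
                raise GenotypeError("panel entry with empty prime name")
            if set(e.profile) != set(self.loci):
                raise GenotypeError(
                    f"panel entry {e.prime_name!r} does not cover exactly "
                    f"the declared loci {self.loci}"
                )
            e.profile = {
                l: (min(p), max(p)) for l, p in e.profile.items()
            }

    @property
    def prime_names(self) -> list[str]:
        return [e.prime_name for e in self.entries]


# -- parsing ---------------------------------------------------------------


def _read_text(source) -> str:
    if hasattr(source, "read"):
        return source.read()
    if isinstance(source, Path):
        return source.read_text()
    if isinstance(source, str):
        if "\n" in source:  # inline content
            return source
        try:
            if Path(source).exists():
                return Path(source).read_text()
        except OSError:
            pass
        return source
    raise TypeError(f"unsupported text source: {type(source)!r}")


def _sniff_delim(header_line: str) -> str:
    return "\t" if "\t" in header_line else ","


def _parse_pair_token(tok: str, row: int, col: str) -> tuple[int, int] | None:
    tok = tok.strip()
    if tok in ("", ".", "NA", "-"):
        return None
    parts = tok.split("/")
    if len(parts) != 2 or not all(p.strip() for p in parts):
        raise GenotypeParseError(
            f"row {row}, locus {col!r}: cell {tok!r} is not 'a/b' "
            "(half-calls are not allowed)"
        )
    try:
        a, b = (int(p) for p in parts)
    except ValueError:
        raise GenotypeParseError(
            f"row {row}, locus {col!r}: non-integer allele token in {tok!r}"
        ) from None
    if a <= 0 or b <= 0:
        raise GenotypeParseError(
            f"row {row}, locus {col!r}: allele lengths must be > 0 in {tok!r}"
        )
    return (min(a, b), max(a, b))


def _parse_single_token(tok: str, row: int, col: str) -> int | None:
    tok = tok.strip()
    if tok in ("", "0", ".", "NA", "-"):
        return None
    try:
        v = int(tok)
    except ValueError:
        raise GenotypeParseError(
            f"row {row}, locus {col!r}: non-integer allele token {tok!r}"
        ) from None
    if v <= 0:
        raise GenotypeParseError(
            f"row {row}, locus {col!r}: allele length must be > 0, got {v}"
        )
    return v


def read_genotype_table(source, dialect: str = "pairs_csv") -> GenotypeMatrix:
    """Read a delimited genotype table.

    Dialects
    --------
    ``pairs_csv``
        One column per locus; cells ``"a/b"`` with missing ``"."``.
        Canonical format.
    ``two_column_csv``
        Two adjacent columns per locus (headers may repeat the locus name or
        carry a ``_1``/``_2`` or ``.1`` suffix); missing coded 0 or blank.

    The first column holds accession IDs; columns whose header starts with
    ``meta:`` are stored as per-accession metadata.  Comma or tab delimited
    (sniffed from the header line).
    """
    if dialect not in ("pairs_csv", "two_column_csv"):
        raise ValueError(f"unknown dialect {dialect!r}")
    text = _read_text(source)
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise GenotypeParseError("empty input")
    delim = _sniff_delim(lines[0])
    rows = list(csv.reader(lines, delimiter=delim))
    header = [h.strip() for h in rows[0]]
    meta_cols = [
        (k, h[len(META_PREFIX):])
        for k, h in enumerate(header)
        if k > 0 and h.startswith(META_PREFIX)
    ]
    data_cols = [
        k for k in range(1, len(header)) if not header[k].startswith(META_PREFIX)
    ]

    if dialect == "pairs_csv":
        locus_ids = [header[k] for k in data_cols]
        _check_unique(locus_ids, "locus")
        pair_cols: list[tuple[str, int, int | None]] = [
            (header[k], k, None) for k in data_cols
        ]
    else:
        if len(data_cols) % 2 != 0:
            raise GenotypeParseError(
                "two_column_csv requires an even number of genotype columns"
            )
        locus_ids = []
        pair_cols = []
        for k1, k2 in zip(data_cols[::2], data_cols[1::2]):
            stem = re.sub(r"([._]\d+|[._][ab12])$", "", header[k1])
            stem2 = re.sub(r"([._]\d+|[._][ab12])$", "", header[k2])
            if stem2 not in (stem, ""):
                raise GenotypeParseError(
                    f"column pair {header[k1]!r}/{header[k2]!r} does not name "
                    "one locus"
                )
            locus_ids.append(stem)
            pair_cols.append((stem, k1, k2))
        _check_unique(locus_ids, "locus")

    accession_ids: list[str] = []
    calls: list[list[tuple[int, int] | None]] = []
    metadata: dict[str, dict[str, str]] = {}
    for r, row in enumerate(rows[1:], start=2):
        if len(row) != len(header):
            raise GenotypeParseError(
                f"row {r}: expected {len(header)} fields, found {len(row)}"
            )
        acc = row[0].strip()
        if not acc:
            raise GenotypeParseError(f"row {r}: empty accession ID")
        accession_ids.append(acc)
        meta = {name: row[k].strip() for k, name in meta_cols if row[k].strip()}
        if meta:
            metadata[acc] = meta
        this: list[tuple[int, int] | None] = []
        for locus, k1, k2 in pair_cols:
            if k2 is None:
                this.append(_parse_pair_token(row[k1], r, locus))
            else:
                u = _parse_single_token(row[k1], r, locus)
                v = _parse_single_token(row[k2], r, locus)
                if (u is None) != (v is None):
                    raise GenotypeParseError(
                        f"row {r}, locus {locus!r}: half-call "
                        f"({row[k1]!r}, {row[k2]!r})"
                    )
                this.append(None if u is None else (min(u, v), max(u, v)))
        calls.append(this)
    _check_unique(accession_ids, "accession")
    return GenotypeMatrix.from_calls(accession_ids, locus_ids, calls, metadata)


def write_pairs_csv(gm: GenotypeMatrix, path=None) -> str:
    """Serialize to the canonical ``pairs_csv`` dialect (min allele first)."""
    meta_keys = sorted({k for m in gm.metadata.values() for k in m})
    buf = io.StringIO()
    w = csv.writer(buf, lineterminator="\n")
    w.writerow(["accession"] + [META_PREFIX + k for k in meta_keys] + gm.locus_ids)
    for i, acc in enumerate(gm.accession_ids):
        meta = gm.metadata.get(acc, {})
        cells = []
        for j in range(gm.n_loci):
            if gm.a1[i, j] == MISSING:
                cells.append(".")
            else:
                cells.append(f"{gm.a1[i, j]}/{gm.a2[i, j]}")
        w.writerow([acc] + [meta.get(k, "") for k in meta_keys] + cells)
    text = buf.getvalue()
    if path is not None:
        Path(path).write_text(text)
    return text


# -- population-genetics exchange format -----------------------------------

STRUCTURE_MISSING = -9


def write_structure_input(
    gm: GenotypeMatrix,
) -> tuple[str, dict[str, dict[str, int]]]:
    """Encode as two-rows-per-individual integer text (missing -9).

    Alleles are recoded per locus to consecutive integer codes (1..n in
    allele-size order).  Returns the text and the recoding table
    ``{locus: {str(allele_bp): code}}`` so the encoding is invertible via
    :func:`decode_structure_input`.
    """
    recoding: dict[str, dict[str, int]] = {}
    code = np.full((gm.n_accessions, gm.n_loci, 2), STRUCTURE_MISSING, dtype=int)
    for j, locus in enumerate(gm.locus_ids):
        table = {a: c for c, a in enumerate(gm.alleles_at(locus), start=1)}
        recoding[locus] = {str(a): c for a, c in table.items()}
        typed = gm.a1[:, j] != MISSING
        code[typed, j, 0] = [table[int(v)] for v in gm.a1[typed, j]]
        code[typed, j, 1] = [table[int(v)] for v in gm.a2[typed, j]]
    out = ["\t".join(gm.locus_ids)]
    for i, acc in enumerate(gm.accession_ids):
        for copy in (0, 1):
            out.append(
                "\t".join([acc] + [str(code[i, j, copy]) for j in range(gm.n_loci)])
            )
    return "\n".join(out) + "\n", recoding


def decode_structure_input(
    text: str, recoding: Mapping[str, Mapping[str, int]]
) -> GenotypeMatrix:
    """Invert :func:`write_structure_input` (metadata is not carried)."""
    lines = [ln for ln in text.splitlines() if ln.strip()]
    locus_ids = lines[0].split("\t")
    decode = {
        locus: {c: int(a) for a, c in table.items()}
        for locus, table in recoding.items()
    }
    if len(lines) % 2 == 0:
        raise GenotypeParseError("expected header plus two rows per individual")
    accession_ids: list[str] = []
    calls: list[list[tuple[int, int] | None]] = []
    for r in range(1, len(lines), 2):
        f1 = lines[r].split("\t")
        f2 = lines[r + 1].split("\t")
        if f1[0] != f2[0]:
            raise GenotypeParseError(
                f"row pair mismatch: {f1[0]!r} vs {f2[0]!r}"
            )
        accession_ids.append(f1[0])
        row: list[tuple[int, int] | None] = []
        for j, locus in enumerate(locus_ids):
            c1, c2 = int(f1[j + 1]), int(f2[j + 1])
            if c1 == STRUCTURE_MISSING or c2 == STRUCTURE_MISSING:
                row.append(None)
            else:
                u, v = decode[locus][c1], decode[locus][c2]
                row.append((min(u, v), max(u, v)))
        calls.append(row)
    return GenotypeMatrix.from_calls(accession_ids, locus_ids, calls)


# -- allele-size standardization -------------------------------------------


@dataclass
class LocusOffset:
    offset: int
    consistency: float  # fraction of anchor alleles agreeing with the offset
    n_anchor_alleles: int


def standardize_alleles(
    gm: GenotypeMatrix,
    panel: ReferenceProfilePanel,
    anchors: Mapping[str, str],
    min_consistency: float = 0.8,
) -> tuple[GenotypeMatrix, dict[str, LocusOffset]]:
    """Shift allele sizes per locus to a reference scale.

    For each locus the integer offset is the mode of
    (reference allele - observed allele) over all anchor accessions and both
    allele copies; offsets are systematic per-locus constants (dye/ladder
    shifts), so the mode is robust to one mistyped anchor.  Loci with no
    anchor information get offset 0 with a warning; a consistency fraction
    below *min_consistency* raises :class:`StandardizationError` listing the
    discordant anchors.  The operation is idempotent.
    """
    panel_by_name = {e.prime_name: e for e in panel.entries}
    for acc, prime in anchors.items():
        if acc not in gm.accession_ids:
            raise GenotypeError(f"anchor accession {acc!r} not in matrix")
        if prime not in panel_by_name:
            raise GenotypeError(f"anchor prime name {prime!r} not in panel")
    offsets: dict[str, LocusOffset] = {}
    new_a1, new_a2 = gm.a1.copy(), gm.a2.copy()
    for j, locus in enumerate(gm.locus_ids):
        diffs: list[int] = []
        origin: list[tuple[str, int]] = []
        if locus in panel.loci:
            for acc, prime in anchors.items():
                i = gm.accession_index(acc)
                if gm.a1[i, j] == MISSING:
                    continue
                ref = panel_by_name[prime].profile[locus]
                obs = (int(gm.a1[i, j]), int(gm.a2[i, j]))
                for k in (0, 1):
                    diffs.append(ref[k] - obs[k])
                    origin.append((acc, ref[k] - obs[k]))
        if not diffs:
            warnings.warn(
                f"locus {locus!r}: no anchor alleles typed; offset 0 assumed",
                stacklevel=2,
            )
            offsets[locus] = LocusOffset(0, float("nan"), 0)
            continue
        counts = Counter(diffs)
        top = max(counts.values())
        # ties: prefer smallest |offset|, then smallest value
        mode = sorted(
            (d for d, c in counts.items() if c == top), key=lambda d: (abs(d), d)
        )[0]
        consistency = counts[mode] / len(diffs)
        if consistency < min_consistency:
            discordant = sorted({acc for acc, d in origin if d != mode})
            raise StandardizationError(
                f"locus {locus!r}: offset {mode:+d} supported by only "
                f"{consistency:.2f} of anchor alleles (< {min_consistency}); "
                f"discordant anchors: {', '.join(discordant)}"
            )
        offsets[locus] = LocusOffset(int(mode), consistency, len(diffs))
        if mode != 0:
            typed = gm.a1[:, j] != MISSING
            new_a1[typed, j] += mode
            new_a2[typed, j] += mode
    out = GenotypeMatrix(
        gm.accession_ids,
        gm.locus_ids,
        new_a1,
        new_a2,
        {k: dict(v) for k, v in gm.metadata.items()},
    )
    return out, offsets


# -- reference panel I/O ---------------------------------------------------


def read_reference_panel(source) -> ReferenceProfilePanel:
    """Read a panel CSV: columns ``prime_name, source, <locus...>`` with
    profile cells as ``a/b``."""
    text = _read_text(source)
    lines = [ln for ln in text.splitlines() if ln.strip()]
    delim = _sniff_delim(lines[0])
    rows = list(csv.reader(lines, delimiter=delim))
    header = [h.strip() for h in rows[0]]
    if len(header) < 3 or header[0] != "prime_name" or header[1] != "source":
        raise GenotypeParseError(
            "panel header must be: prime_name, source, <locus columns>"
        )
    loci = header[2:]
    entries = []
    for r, row in enumerate(rows[1:], start=2):
        profile = {}
        for k, locus in enumerate(loci, start=2):
            pair = _parse_pair_token(row[k], r, locus)
            if pair is None:
                raise GenotypeParseError(
                    f"row {r}: panel entry {row[0]!r} missing locus {locus!r}"
                )
            profile[locus] = pair
        entries.append(ReferenceProfile(row[0].strip(), profile, row[1].strip()))
    return ReferenceProfilePanel(loci, entries)


def write_reference_panel(panel: ReferenceProfilePanel, path=None) -> str:
    buf = io.StringIO()
    w = csv.writer(buf, lineterminator="\n")
    w.writerow(["prime_name", "source"] + panel.loci)
    for e in panel.entries:
        w.writerow(
            [e.prime_name, e.source]
            + [f"{e.profile[l][0]}/{e.profile[l][1]}" for l in panel.loci]
        )
    text = buf.getvalue()
    if path is not None:
        Path(path).write_text(text)
    return text
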