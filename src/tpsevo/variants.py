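"""In-silico construction of enzyme sequence variants.

Covers the variant types used to dissect functional evolution: alternative
ancestors in which uncertain sites carry their second-best reconstructed
residue (AltAll, or AltAlpha when restricted to active-site regions),
point mutants named by reference coordinates (e.g. A723T), and chimeras in
which contiguous regions are swapped between a recipient and a donor
sequence.  Also provides masked Hamming distances between aligned
sequences.

Coordinates are 1-based and inclusive throughout.  Reference numbering
(e.g. positions numbered along a full-length reference enzyme) is mapped
to alignment columns explicitly via :class:`ReferenceNumbering`, never by
positional guessing.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass

import numpy as np

from .ancestral import AncestralSequence, SitePosteriorTable, ALPHABET, MISSING_CHARS
from .errors import InputError, StaleVariantSpecError


# ---------------------------------------------------------------------------
# Coordinates
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReferenceNumbering:
    """Bijection between 1-based alignment columns and reference positions.

    Built from the aligned reference sequence: non-gap columns are numbered
    consecutively from ``start``.
    """

    col_to_ref: dict
    ref_to_col: dict

    @classmethod
    def from_aligned_reference(cls, aligned_seq: str, start: int = 1) -> "ReferenceNumbering":
        c2r, r2c = {}, {}
        pos = start
        for col, ch in enumerate(aligned_seq, start=1):
            if ch not in MISSING_CHARS:
                c2r[col] = pos
                r2c[pos] = col
                pos += 1
        return cls(c2r, r2c)

    @classmethod
    def identity(cls, length: int, start: int = 1) -> "ReferenceNumbering":
        """Numbering for ungapped sequences: column i is reference position i."""
        rng = {i: i - 1 + start for i in range(1, length + 1)}
        return cls(rng, {v: k for k, v in rng.items()})

    def to_column(self, ref_pos: int) -> int:
        try:
            return self.ref_to_col[ref_pos]
        except KeyError:
            raise InputError(f"reference position {ref_pos} is not mapped to "
                             "any alignment column") from None

    def to_reference(self, col: int) -> int:
        try:
            return self.col_to_ref[col]
        except KeyError:
            raise InputError(f"alignment column {col} has no reference "
                             "position (gap in reference)") from None


@dataclass(frozen=True)
class RegionSet:
    """Named, non-overlapping sets of 1-based inclusive reference intervals."""

    regions: dict  # name -> tuple of (start, end)

    def __post_init__(self):
        seen = {}
        norm = {}
        for name, ivals in self.regions.items():
            ivals = tuple(sorted((int(a), int(b)) for a, b in ivals))
            for a, b in ivals:
                if a > b:
                    raise InputError(f"region {name!r}: interval ({a}, {b}) is reversed")
                for p in range(a, b + 1):
                    if p in seen:
                        raise InputError(
                            f"regions {seen[p]!r} and {name!r} overlap at position {p}")
                    seen[p] = name
            norm[name] = ivals
        object.__setattr__(self, "regions", norm)

    def positions(self, name: str) -> frozenset:
        if name not in self.regions:
            raise InputError(f"unknown region {name!r}; known: {sorted(self.regions)}")
        return frozenset(p for a, b in self.regions[name] for p in range(a, b + 1))

    def mask(self, names) -> frozenset:
        out = frozenset()
        for n in names:
            out |= self.positions(n)
        return out

    @classmethod
    def from_json(cls, text_or_path) -> "RegionSet":
        try:
            data = json.loads(text_or_path)
        except (json.JSONDecodeError, TypeError):
            with open(text_or_path) as fh:
                data = json.load(fh)
        return cls({name: [tuple(iv) for iv in ivals] for name, ivals in data.items()})


# ---------------------------------------------------------------------------
# Variant specifications
# ---------------------------------------------------------------------------

_CODE_RE = re.compile(r"^M(?P<background>\d+)-(?P<variant>\d+)\w*$")
_EDIT_RE = re.compile(r"^([A-Za-z])(\d+)([A-Za-z])$")


@dataclass(frozen=True)
class PointEdit:
    position: int   # reference coordinate
    ancestral: str  # residue expected in the background
    derived: str

    @classmethod
    def parse(cls, text: str) -> "PointEdit":
        m = _EDIT_RE.match(text.strip())
        if not m:
            raise InputError(f"cannot parse point edit {text!r} (expected e.g. 'A723T')")
        return cls(int(m.group(2)), m.group(1).upper(), m.group(3).upper())

    def __str__(self):
        return f"{self.ancestral}{self.position}{self.derived}"


@dataclass(frozen=True)
class VariantSpec:
    """A named variant: point edits and/or region swaps on a background."""

    code: str                 # e.g. "M9-5"
    background: str           # background enzyme id
    edits: tuple = ()         # PointEdit instances
    swaps: tuple = ()         # (region name, donor id)

    def __post_init__(self):
        m = _CODE_RE.match(self.code)
        if not m:
            raise InputError(f"variant code {self.code!r} does not parse as 'M<n>-<m>'")
        object.__setattr__(self, "edits", tuple(
            e if isinstance(e, PointEdit) else PointEdit.parse(e) for e in self.edits))
        object.__setattr__(self, "swaps", tuple(tuple(s) for s in self.swaps))

    @property
    def background_number(self) -> int:
        return int(_CODE_RE.match(self.code).group("background"))

    @classmethod
    def from_dict(cls, d: dict) -> "VariantSpec":
        edits = d.get("edits", "")
        if isinstance(edits, str):
            edits = [e for e in edits.split(";") if e]
        swaps = d.get("swaps", "")
        if isinstance(swaps, str):
            swaps = [tuple(s.split(":", 1)) for s in swaps.split(";") if s]
        return cls(code=d["code"], background=d["background"],
                   edits=tuple(edits), swaps=tuple(swaps))


def load_variant_specs(path) -> list[VariantSpec]:
    """Read variant specs from JSON (list of objects) or CSV."""
    path = str(path)
    if path.endswith(".json"):
        with open(path) as fh:
            return [VariantSpec.from_dict(d) for d in json.load(fh)]
    import pandas as pd
    df = pd.read_csv(path, dtype=str).fillna("")
    return [VariantSpec.from_dict(row._asdict() if hasattr(row, "_asdict") else dict(row))
            for _, row in df.iterrows()]


# ---------------------------------------------------------------------------
# Construction operations
# ---------------------------------------------------------------------------

def _resolve(pos: int, numbering: ReferenceNumbering | None, length: int) -> int:
    """Reference position -> 0-based sequence index."""
    col = numbering.to_column(pos) if numbering is not None else pos
    if not 1 <= col <= length:
        raise InputError(f"position {pos} maps to column {col}, outside 1..{length}")
    return col - 1


def build_altall(table: SitePosteriorTable, ml: AncestralSequence,
                 threshold: float = 0.2,
                 site_mask=None,
                 numbering: ReferenceNumbering | None = None) -> str:
    """Alternative ancestor carrying second-best residues at uncertain sites.

    At every site where the second-best posterior exceeds ``threshold``
    (strictly), the ML residue is replaced by the second-best one.  With a
    ``site_mask`` of reference positions, only those sites are eligible
    (the AltAlpha construction restricted to the active-site regions).
    """
    if not 0 < threshold < 1:
        raise InputError(f"threshold must be in (0, 1), got {threshold}")
    L = len(ml.sequence)
    eligible = None
    if site_mask is not None:
        eligible = {_resolve(p, numbering, L) for p in site_mask}
    probs = table.probs
    order = np.argsort(-probs, axis=1, kind="stable")  # ties: lower index first
    seq = list(ml.sequence)
    for i in range(L):
        if eligible is not None and i not in eligible:
            continue
        second = order[i, 1]
        if probs[i, second] > threshold:
            seq[i] = ALPHABET[second]
    return "".join(seq)


def apply_point_mutations(background: str, edits,
                          numbering: ReferenceNumbering | None = None) -> str:
    """Apply point edits, verifying the expected ancestral residue at each.

    A mismatch raises :class:`StaleVariantSpecError` naming the position and
    both residues: specs written against one reconstruction must not be
    silently applied to another.
    """
    seq = list(background)
    for e in edits:
        if not isinstance(e, PointEdit):
            e = PointEdit.parse(e)
        i = _resolve(e.position, numbering, len(seq))
        if seq[i] != e.ancestral:
            raise StaleVariantSpecError(e.position, e.ancestral, seq[i])
        seq[i] = e.derived
    return "".join(seq)


def build_chimera(recipient: str, donor: str, regions: RegionSet,
                  selected,
                  numbering: ReferenceNumbering | None = None) -> str:
    """Replace the selected regions of the recipient with the donor's residues."""
    if len(recipient) != len(donor):
        raise InputError(f"recipient and donor lengths differ "
                         f"({len(recipient)} vs {len(donor)}); sequences must be aligned")
    seq = list(recipient)
    for pos in regions.mask(selected):
        i = _resolve(pos, numbering, len(seq))
        seq[i] = donor[i]
    return "".join(seq)


def apply_variant(spec: VariantSpec, backgrounds: dict, regions: RegionSet | None = None,
                  numbering: ReferenceNumbering | None = None) -> str:
    """Materialise a VariantSpec: region swaps first, then point edits."""
    seq = backgrounds[spec.background]
    for region, donor in spec.swaps:
        if regions is None:
            raise InputError(f"variant {spec.code} has region swaps but no "
                             "RegionSet was provided")
        seq = build_chimera(seq, backgrounds[donor], regions, [region], numbering)
    return apply_point_mutations(seq, spec.edits, numbering)


def hamming_distance(seq_a: str, seq_b: str, site_mask=None,
                     numbering: ReferenceNumbering | None = None) -> int:
    """Count differing positions between aligned sequences.

    Columns where either sequence carries a gap/ambiguity character are
    excluded (a gap against a residue is never counted as a difference).
    ``site_mask`` restricts the count to the given reference positions.
    """
    if len(seq_a) != len(seq_b):
        raise InputError(f"sequence lengths differ ({len(seq_a)} vs {len(seq_b)})")
    if site_mask is not None:
        idx = sorted(_resolve(p, numbering, len(seq_a)) for p in site_mask)
    else:
        idx = range(len(seq_a))
    n = 0
    for i in idx:
        a, b = seq_a[i].upper(), seq_b[i].upper()
        if a in MISSING_CHARS or b in MISSING_CHARS:
            continue
        if a != b:
            n += 1
    return n
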