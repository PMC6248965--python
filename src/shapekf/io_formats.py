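"""Readers and writers for SHAPE reactivity profiles and RNA secondary structures.

Profiles travel on disk in the two-column convention used by RNAstructure
and most probing pipelines: a 1-based position and a reactivity, with -999
marking a nucleotide without a score. Secondary structures are accepted as
CT files or nested dot-bracket strings.

Internally a profile is a numpy float array where missing entries are NaN;
all user-facing positions are 1-based.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from os import PathLike
from typing import Iterable, Union

import numpy as np

#: On-disk sentinel for a nucleotide without a reactivity score.
MISSING_SENTINEL = -999.0

#: Any reactivity at or below this value is treated as missing on read,
#: tolerating -999 / -999.0 / -1000 dialects.
MISSING_THRESHOLD = -500.0


class FormatError(ValueError):
    """A file violates the structural contract of its format."""


class DomainError(ValueError):
    """An operation received a profile in the wrong domain (data vs log)."""


@dataclass(frozen=True)
class ReactivityProfile:
    """Per-nucleotide reactivities for one RNA.

    Parameters
    ----------
    reactivities :
        Float array of length M; NaN marks a missing value. In the log
        domain every non-missing entry must be finite.
    rna_id :
        Free-text label for the RNA.
    domain :
        ``"data"`` for raw reactivities, ``"log"`` for their natural log.
    """

    reactivities: np.ndarray
    rna_id: str = ""
    domain: str = "data"

    def __post_init__(self) -> None:
        arr = np.asarray(self.reactivities, dtype=float)
        if arr.ndim != 1:
            raise ValueError("reactivities must be one-dimensional")
        if arr.size == 0:
            raise ValueError("profile must contain at least one nucleotide")
        if self.domain not in ("data", "log"):
            raise ValueError(f"unknown domain {self.domain!r}")
        if self.domain == "log":
            finite = arr[~np.isnan(arr)]
            if finite.size and not np.all(np.isfinite(finite)):
                raise DomainError("log-domain profile contains non-finite values")
        object.__setattr__(self, "reactivities", arr)

    def __len__(self) -> int:
        return int(self.reactivities.size)

    @property
    def length(self) -> int:
        return len(self)

    @property
    def missing_mask(self) -> np.ndarray:
        """Boolean mask, True where the reactivity is missing."""
        return np.isnan(self.reactivities)

    @property
    def values(self) -> np.ndarray:
        """Non-missing reactivities, in position order."""
        return self.reactivities[~self.missing_mask]

    def with_values(self, reactivities: np.ndarray, domain: str | None = None) -> "ReactivityProfile":
        """Copy of this profile with new values (and optionally a new domain)."""
        return replace(
            self,
            reactivities=np.asarray(reactivities, dtype=float),
            domain=self.domain if domain is None else domain,
        )


@dataclass(frozen=True)
class SecondaryStructure:
    """A set of base pairs for an RNA of known length.

    Pairs are unordered, stored as (i, j) with 1 <= i < j <= length, and
    each position may participate in at most one pair.
    """

    length: int
    pairs: frozenset[tuple[int, int]] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("structure length must be positive")
        norm = frozenset((min(i, j), max(i, j)) for i, j in self.pairs)
        seen: set[int] = set()
        for i, j in norm:
            if i == j:
                raise ValueError(f"position {i} paired with itself")
            if not (1 <= i < j <= self.length):
                raise ValueError(f"pair ({i}, {j}) outside 1..{self.length}")
            for p in (i, j):
                if p in seen:
                    raise ValueError(f"position {p} appears in more than one pair")
                seen.add(p)
        object.__setattr__(self, "pairs", norm)

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)


PathType = Union[str, PathLike]


def read_shape(path: PathType) -> ReactivityProfile:
    """Read a two-column SHAPE reactivity file.

    Columns are 1-based position and reactivity, whitespace-delimited.
    Positions must be contiguous from 1. Reactivities at or below -500
    (conventionally exactly -999) are recorded as missing.
    """
    positions: list[int] = []
    values: list[float] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 2:
                raise FormatError(f"{path}: line {lineno}: expected two columns")
            try:
                pos = int(fields[0])
                val = float(fields[1])
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: non-numeric field") from exc
            positions.append(pos)
            values.append(val)
    if not positions:
        raise FormatError(f"{path}: empty profile")
    expected = list(range(1, len(positions) + 1))
    if positions != expected:
        raise FormatError(
            f"{path}: positions must be contiguous and ascending from 1 "
            f"(got {positions[:5]}...)"
        )
    arr = np.array(values, dtype=float)
    arr[arr <= MISSING_THRESHOLD] = np.nan
    return ReactivityProfile(arr, rna_id=str(path))


def write_shape(profile: ReactivityProfile, path: PathType) -> None:
    """Write a data-domain profile in the two-column SHAPE convention."""
    if profile.domain != "data":
        raise DomainError("write_shape expects a data-domain profile")
    with open(path, "w") as fh:
        for pos, val in enumerate(profile.reactivities, start=1):
            if math.isnan(val):
                fh.write(f"{pos}\t{MISSING_SENTINEL:g}\n")
            else:
                fh.write(f"{pos}\t{val:.6g}\n")


def read_ct(path: PathType) -> SecondaryStructure:
    """Read a secondary structure from a CT file.

    Standard six-column body: index, base, previous index, next index,
    pairing partner (0 = unpaired), natural numbering. The header line
    starts with the sequence length. Pairing must be symmetric.
    """
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    if not lines:
        raise FormatError(f"{path}: empty CT file")
    header = lines[0].split()
    try:
        length = int(header[0])
    except (IndexError, ValueError) as exc:
        raise FormatError(f"{path}: CT header must start with the length") from exc
    if length < 1 or len(lines) - 1 < length:
        raise FormatError(f"{path}: CT body shorter than declared length {length}")

    partner = np.zeros(length + 1, dtype=int)
    for row in lines[1 : length + 1]:
        fields = row.split()
        if len(fields) < 6:
            raise FormatError(f"{path}: CT row has fewer than 6 columns: {row!r}")
        try:
            idx = int(fields[0])
            pair = int(fields[4])
        except ValueError as exc:
            raise FormatError(f"{path}: non-numeric CT field in {row!r}") from exc
        if not (1 <= idx <= length):
            raise FormatError(f"{path}: CT index {idx} outside 1..{length}")
        if pair < 0 or pair > length:
            raise FormatError(f"{path}: pairing index {pair} outside 0..{length}")
        partner[idx] = pair

    pairs: set[tuple[int, int]] = set()
    for i in range(1, length + 1):
        j = partner[i]
        if j == 0:
            continue
        if partner[j] != i:
            raise FormatError(
                f"{path}: asymmetric pairing — {i} pairs {j} but {j} pairs {partner[j]}"
            )
        pairs.add((min(i, j), max(i, j)))
    return SecondaryStructure(length=length, pairs=frozenset(pairs))


def read_dotbracket(text: str) -> SecondaryStructure:
    """Decode a nested dot-bracket string over the alphabet ``. ( )``.

    Pseudoknot alphabets ([], {}, letters) are not supported; such
    structures must be provided as CT files.
    """
    text = text.strip()
    if not text:
        raise FormatError("empty dot-bracket string")
    stack: list[int] = []
    pairs: set[tuple[int, int]] = set()
    for pos, ch in enumerate(text, start=1):
        if ch == "(":
            stack.append(pos)
        elif ch == ")":
            if not stack:
                raise FormatError(f"unbalanced ')' at position {pos}")
            i = stack.pop()
            pairs.add((i, pos))
        elif ch != ".":
            raise FormatError(f"unsupported character {ch!r} at position {pos}")
    if stack:
        raise FormatError(f"unbalanced '(' at position {stack[-1]}")
    return SecondaryStructure(length=len(text), pairs=frozenset(pairs))


def profiles_equal(a: ReactivityProfile, b: ReactivityProfile, rtol: float = 1e-9) -> bool:
    """Value equality of two profiles, treating NaN as equal to NaN."""
    if len(a) != len(b) or a.domain != b.domain:
        return False
    am, bm = a.missing_mask, b.missing_mask
    if not np.array_equal(am, bm):
        return False
    return bool(np.allclose(a.reactivities[~am], b.reactivities[~bm], rtol=rtol))
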