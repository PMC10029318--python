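"""Canonical motif classes for tandem-repeat units.

A microsatellite motif is reported on whichever strand the scanner happened
to read, and in whichever rotational phase the run happened to start.  For
cross-genome bookkeeping every unit is mapped to a *canonical class*: the
equivalence class of the unit under cyclic rotation and reverse
complementation, named by its lexicographically smallest member.  This
reproduces the conventional strand-pair labels used in the repeat
literature — TC, CT, GA and AG all belong to the class "AG" (the (AG/CT)n
motif), AGT maps to "ACT" (ACT/AGT), AGGGTT to "AACCCT" (AACCCT/AGGGTT).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_VALID = frozenset("ACGT")


class InvalidAlphabetError(ValueError):
    """Raised when a motif contains characters outside A, C, G, T."""


def revcomp(seq: str) -> str:
    """Reverse complement of an A/C/G/T string."""
    return seq.translate(_COMPLEMENT)[::-1]


def _rotations(unit: str) -> list[str]:
    return [unit[i:] + unit[:i] for i in range(len(unit))]


@dataclass(frozen=True)
class MotifClass:
    """Strand-pair equivalence class of a repeat unit.

    ``canonical`` is the lexicographically smallest string among all
    rotations of the unit and all rotations of its reverse complement;
    ``members`` is the full equivalence class.
    """

    canonical: str
    members: frozenset[str] = field(compare=False)

    @property
    def unit_size(self) -> int:
        return len(self.canonical)

    @property
    def label(self) -> str:
        """Strand-pair label, e.g. ``AG/CT``."""
        rc = revcomp(self.canonical)
        return self.canonical if rc == self.canonical else f"{self.canonical}/{rc}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.canonical


def is_primitive(unit: str) -> bool:
    """True iff *unit* is not a whole-number repetition of a shorter string.

    (AT)x7 must be counted as a dinucleotide run, never as an "ATAT"
    tetranucleotide run; non-primitive units are rejected everywhere.
    """
    n = len(unit)
    if n == 0:
        raise ValueError("empty unit")
    for d in range(1, n // 2 + 1):
        if n % d == 0 and unit == unit[:d] * (n // d):
            return False
    return True


@lru_cache(maxsize=65536)
def canonical_motif(unit: str) -> MotifClass:
    """Map a repeat unit to its canonical strand-pair class.

    Parameters
    ----------
    unit
        Repeat unit, 1-6 bp, A/C/G/T only (case-insensitive).

    Raises
    ------
    InvalidAlphabetError
        If the unit contains a character outside A, C, G, T.
    """
    unit = unit.upper()
    if not unit or not _VALID.issuperset(unit):
        raise InvalidAlphabetError(f"motif {unit!r} contains non-ACGT characters")
    members = frozenset(_rotations(unit) + _rotations(revcomp(unit)))
    return MotifClass(canonical=min(members), members=members)
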