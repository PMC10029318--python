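"""Perfect and compound SSR detection.

The scanner finds every maximal perfect tandem run of a primitive 1-6 bp
unit whose repeat count meets a motif-size-specific minimum — by default 10
repeats for mononucleotides, 7 for di-, 6 for tri-, 5 for tetra- and 4 for
penta- and hexanucleotides, the thresholds conventionally used for plant
genome microsatellite surveys.  Runs of different unit sizes that overlap
are resolved greedily (longest first), and surviving runs separated by at
most ``max_interruption`` bases are merged into compound loci, mirroring
the behaviour of the classic MISA screen.

Coordinates are 0-based half-open internally and 1-based inclusive in every
reported/serialized form.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .motifs import MotifClass, canonical_motif, is_primitive

DEFAULT_MIN_REPEATS: dict[int, int] = {1: 10, 2: 7, 3: 6, 4: 5, 5: 4, 6: 4}

_BASE_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_CODE[_b] = _i


@dataclass(frozen=True)
class ScanConfig:
    """Scanner thresholds.

    Parameters
    ----------
    min_repeats
        Minimum repeat count per unit size (1..6).
    max_interruption
        Maximum gap (bp) between neighbouring runs merged into one
        compound locus.
    motif_lengths
        Unit sizes to scan.
    """

    min_repeats: dict[int, int] = field(
        default_factory=lambda: dict(DEFAULT_MIN_REPEATS)
    )
    max_interruption: int = 100
    motif_lengths: frozenset[int] = frozenset(range(1, 7))

    def __post_init__(self) -> None:
        if self.max_interruption < 0:
            raise ValueError("max_interruption must be >= 0")
        for k in self.motif_lengths:
            if k not in self.min_repeats:
                raise ValueError(f"no min_repeats threshold for unit size {k}")
            if self.min_repeats[k] < 2:
                raise ValueError("min_repeats values must be >= 2")


@dataclass(frozen=True)
class SSRLocus:
    """One detected repeat locus.

    ``start``/``end`` are 1-based inclusive.  For perfect loci
    ``length == n_repeats * len(motif)``; compound loci span their member
    runs plus interruptions, with the members kept in ``sub_loci``.
    """

    seq_id: str
    start: int
    end: int
    motif: str
    motif_class: MotifClass
    n_repeats: int
    kind: str = "perfect"  # "perfect" | "compound"
    sub_loci: tuple["SSRLocus", ...] = ()

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def unit_size(self) -> int:
        return len(self.motif)

    @property
    def repeat_bp(self) -> int:
        """Bases belonging to repeat runs (excludes compound interruptions)."""
        if self.kind == "perfect":
            return self.length
        return sum(s.length for s in self.sub_loci)

    def repeat_sequence(self) -> str:
        """Reference-strand sequence of the repeat runs only."""
        if self.kind == "perfect":
            return (self.motif * self.n_repeats)[: self.length]
        return "".join(s.repeat_sequence() for s in self.sub_loci)


def scan_sequence(
    seq: str, cfg: ScanConfig | None = None, seq_id: str = "seq"
) -> list[SSRLocus]:
    """Find all maximal perfect tandem runs (pre-merge).

    A run is reported once, anchored at the leftmost base of its maximal
    periodic region; trailing partial units do not extend it.  Non-ACGT
    characters (N, IUPAC codes) terminate runs; lowercase input is
    uppercased.  Runs whose unit is a repetition of a shorter unit are
    reported only at the shorter (primitive) unit size.
    """
    cfg = cfg or ScanConfig()
    if not seq:
        return []
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    code = _BASE_CODE[arr]
    valid = code >= 0
    n = arr.size
    loci: list[SSRLocus] = []
    useq = seq.upper()
    for k in sorted(cfg.motif_lengths):
        if n < 2 * k:
            continue
        min_rep = cfg.min_repeats[k]
        # match[x] True when position x+k repeats position x and both are ACGT
        match = (arr[k:] == arr[:-k]) & valid[k:] & valid[:-k]
        # a maximal True-run [a, b) in match <=> periodic region [a, b + k)
        padded = np.concatenate(([False], match, [False]))
        edges = np.flatnonzero(padded[1:] != padded[:-1])
        starts, ends = edges[0::2], edges[1::2]
        for a, b in zip(starts, ends):
            region_len = b - a + k
            n_rep = region_len // k
            if n_rep < min_rep:
                continue
            unit = useq[a : a + k]
            if not is_primitive(unit):
                continue
            loci.append(
                SSRLocus(
                    seq_id=seq_id,
                    start=int(a) + 1,
                    end=int(a) + int(n_rep) * k,
                    motif=unit,
                    motif_class=canonical_motif(unit),
                    n_repeats=int(n_rep),
                )
            )
    loci.sort(key=lambda l: (l.start, l.unit_size))
    return loci


def resolve_and_merge(runs: list[SSRLocus], cfg: ScanConfig | None = None) -> list[SSRLocus]:
    """Resolve overlaps between runs and merge near-adjacent runs.

    Overlapping runs (necessarily of different unit sizes or phases) are
    resolved greedily: longest total length first, ties to the smaller
    unit size, then leftmost.  Surviving runs whose gap is at most
    ``cfg.max_interruption`` bp become one compound locus preserving the
    member runs.  Output is sorted by start and mutually non-overlapping.
    """
    cfg = cfg or ScanConfig()
    if not runs:
        return []
    order = sorted(runs, key=lambda l: (-l.length, l.unit_size, l.start))
    kept: list[SSRLocus] = []
    occupied: list[tuple[int, int]] = []
    for run in order:
        if any(run.start <= e and run.end >= s for s, e in occupied):
            continue
        kept.append(run)
        occupied.append((run.start, run.end))
    kept.sort(key=lambda l: l.start)

    merged: list[SSRLocus] = []
    group: list[SSRLocus] = []
    for run in kept:
        if group and run.start - group[-1].end - 1 <= cfg.max_interruption:
            group.append(run)
        else:
            if group:
                merged.append(_emit(group))
            group = [run]
    if group:
        merged.append(_emit(group))
    return merged


def _emit(group: list[SSRLocus]) -> SSRLocus:
    if len(group) == 1:
        return group[0]
    first = group[0]
    return SSRLocus(
        seq_id=first.seq_id,
        start=first.start,
        end=group[-1].end,
        motif=first.motif,
        motif_class=first.motif_class,
        n_repeats=sum(g.n_repeats for g in group),
        kind="compound",
        sub_loci=tuple(group),
    )


def scan(seq: str, cfg: ScanConfig | None = None, seq_id: str = "seq") -> list[SSRLocus]:
    """Full per-sequence detection: maximal runs, then resolution/merging."""
    cfg = cfg or ScanConfig()
    return resolve_and_merge(scan_sequence(seq, cfg, seq_id), cfg)


def scan_genome(
    sequences: dict[str, str], cfg: ScanConfig | None = None
) -> list[SSRLocus]:
    """Scan every sequence of a genome; loci ordered by (seq_id, start)."""
    cfg = cfg or ScanConfig()
    out: list[SSRLocus] = []
    for seq_id, seq in sequences.items():
        out.extend(scan(seq, cfg, seq_id))
    return out
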