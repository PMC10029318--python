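"""Per-motif descriptive statistics: GC content, allele spectra, length classes.

GC content is computed over repeat-run bases only (compound interruptions
excluded — GC is a property of the repeat DNA itself), while length-class
binning follows the full locus span as the screen reports it.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass

import pandas as pd

from .scan import SSRLocus

LENGTH_BINS: tuple[str, ...] = (
    "10-20", "21-30", "31-40", "41-50", "51-60",
    "61-70", "71-80", "81-90", "91-100", "101+",
)


def gc_content(loci: list[SSRLocus], group_by: str = "unit_size") -> dict:
    """Pooled GC percentage per group of loci.

    Parameters
    ----------
    loci
        Detected loci (perfect or compound); repeat-run bases only are
        counted.
    group_by
        ``"unit_size"`` (1..6) or ``"motif_class"`` (canonical string).

    Returns
    -------
    dict mapping group key to ``100 * (G+C)/(total bases)``.  Empty groups
    are simply absent (never reported as 0).
    """
    gc: Counter = Counter()
    total: Counter = Counter()
    for loc in loci:
        key = loc.unit_size if group_by == "unit_size" else loc.motif_class.canonical
        s = loc.repeat_sequence()
        gc[key] += s.count("G") + s.count("C")
        total[key] += len(s)
    return {k: 100.0 * gc[k] / total[k] for k in total if total[k] > 0}


@dataclass(frozen=True)
class AlleleSpectrum:
    """Repeat-count (allele) frequency spectrum of one motif class."""

    motif_class: str
    frequencies: dict[int, float]

    @property
    def top_two_share(self) -> float:
        """Cumulative share (%) of the two most frequent repeat counts."""
        top = sorted(self.frequencies.values(), reverse=True)[:2]
        return 100.0 * sum(top)


def allele_spectrum(loci: list[SSRLocus], motif_class: str) -> AlleleSpectrum:
    """Normalized histogram of repeat counts for one canonical class.

    Compound loci contribute each member run separately (each run is one
    allele observation of its own class).
    """
    counts: Counter = Counter()
    for loc in loci:
        parts = loc.sub_loci if loc.kind == "compound" else (loc,)
        for p in parts:
            if p.motif_class.canonical == motif_class:
                counts[p.n_repeats] += 1
    n = sum(counts.values())
    if n == 0:
        raise ValueError(f"no loci of class {motif_class!r}")
    return AlleleSpectrum(
        motif_class=motif_class,
        frequencies={k: v / n for k, v in sorted(counts.items())},
    )


def length_bin(length: int) -> str:
    """Bin label for a locus length (>= 10 bp).

    The first bin spans 10-20 inclusive (11 lengths, as conventionally
    printed), subsequent bins 10 lengths each, 101+ open-ended.
    """
    if length < 10:
        raise ValueError(f"locus length {length} < 10 bp cannot be binned")
    if length <= 20:
        return "10-20"
    if length > 100:
        return "101+"
    return LENGTH_BINS[(length - 1) // 10 - 1]


def length_class_histogram(loci: list[SSRLocus]) -> pd.DataFrame:
    """Locus counts per length bin per unit size.

    Rows are the ten bin labels in order; columns are unit sizes present.
    Every locus falls in exactly one bin, so each column sums to the number
    of loci of that unit size.
    """
    table: dict[int, Counter] = defaultdict(Counter)
    for loc in loci:
        table[loc.unit_size][length_bin(loc.length)] += 1
    df = pd.DataFrame(
        {k: [table[k].get(b, 0) for b in LENGTH_BINS] for k in sorted(table)},
        index=list(LENGTH_BINS),
    )
    df.index.name = "length_bin"
    return df
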