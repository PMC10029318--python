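"""Genomic-region partition (CDS / UTR / intron / intergenic) and SSR assignment.

Annotation features are flattened, across all transcripts, into four labels
that exactly partition each sequence:

* ``CDS`` — union of CDS records;
* ``UTR`` — union of explicit UTR records if any exist (5' and 3' pooled),
  otherwise exon-minus-CDS; minus CDS (label priority CDS > UTR);
* ``intron`` — gene spans minus CDS and UTR;
* ``intergenic`` — everything outside gene spans.

SSR loci are assigned to the label with which they share the most bases;
ties go CDS > UTR > intron > intergenic.  Densities are bp of SSR per Mbp
of the *label's own* length, which is what makes the strong genic
enrichment visible despite intergenic DNA carrying most loci by count.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass, field

import pandas as pd

from . import intervals as iv
from .scan import SSRLocus

REGION_LABELS = ("CDS", "UTR", "intron", "intergenic")


@dataclass(frozen=True)
class Feature:
    """One annotation record (1-based inclusive, GFF/GTF convention)."""

    seq_id: str
    kind: str  # gene, mRNA, exon, CDS, five_prime_UTR, three_prime_UTR, ...
    start: int
    end: int
    attributes: str = ""


@dataclass
class RegionSet:
    """Disjoint per-label interval sets that partition the genome.

    ``intervals[label][seq_id]`` is a sorted disjoint list of 0-based
    half-open intervals.
    """

    intervals: dict[str, dict[str, list[tuple[int, int]]]]
    genome_lengths: dict[str, int]
    _starts: dict = field(default_factory=dict, repr=False)

    @property
    def total_lengths(self) -> dict[str, int]:
        return {
            label: sum(iv.total_length(ivs) for ivs in per_seq.values())
            for label, per_seq in self.intervals.items()
        }

    @property
    def genome_length(self) -> int:
        return sum(self.genome_lengths.values())

    def overlap_bp(self, label: str, seq_id: str, start0: int, end0: int) -> int:
        """Bases of [start0, end0) (0-based half-open) covered by a label."""
        ivs = self.intervals[label].get(seq_id, [])
        if not ivs:
            return 0
        key = (label, seq_id)
        starts = self._starts.get(key)
        if starts is None:
            starts = [s for s, _ in ivs]
            self._starts[key] = starts
        i = max(bisect_right(starts, start0) - 1, 0)
        bp = 0
        while i < len(ivs) and ivs[i][0] < end0:
            s, e = ivs[i]
            bp += max(0, min(e, end0) - max(s, start0))
            i += 1
        return bp


_UTR_KINDS = {
    "five_prime_utr", "three_prime_utr", "utr", "5utr", "3utr",
    "five_prime_UTR", "three_prime_UTR", "UTR",
}


def build_region_set(
    features: list[Feature], genome_lengths: dict[str, int]
) -> RegionSet:
    """Flatten annotation features into the four-label genome partition.

    Raises ``ValueError`` when a feature extends beyond its sequence or
    names a sequence with no known length.
    """
    per_seq: dict[str, dict[str, list[tuple[int, int]]]] = {}
    for f in features:
        if f.seq_id not in genome_lengths:
            raise ValueError(f"feature on unknown sequence {f.seq_id!r}")
        if f.end > genome_lengths[f.seq_id] or f.start < 1:
            raise ValueError(
                f"feature {f.kind} {f.start}-{f.end} outside {f.seq_id} "
                f"(length {genome_lengths[f.seq_id]})"
            )
        bucket = per_seq.setdefault(f.seq_id, {"gene": [], "exon": [], "CDS": [], "UTR": []})
        kind = f.kind.lower()
        if kind in ("gene", "transcript", "mrna"):
            # transcript/mRNA spans stand in for gene spans when genes absent
            bucket["gene"].append((f.start - 1, f.end))
        elif kind == "exon":
            bucket["exon"].append((f.start - 1, f.end))
        elif kind == "cds":
            bucket["CDS"].append((f.start - 1, f.end))
        elif kind in {k.lower() for k in _UTR_KINDS}:
            bucket["UTR"].append((f.start - 1, f.end))

    out: dict[str, dict[str, list[tuple[int, int]]]] = {
        label: {} for label in REGION_LABELS
    }
    for seq_id, length in genome_lengths.items():
        b = per_seq.get(seq_id, {"gene": [], "exon": [], "CDS": [], "UTR": []})
        cds = iv.merge(b["CDS"])
        gene = iv.merge(b["gene"] + b["exon"] + b["CDS"] + b["UTR"])
        utr_raw = iv.merge(b["UTR"]) if b["UTR"] else iv.subtract(b["exon"], cds)
        utr = iv.subtract(utr_raw, cds)
        intron = iv.subtract(gene, cds + utr)
        intergenic = iv.subtract([(0, length)], gene)
        out["CDS"][seq_id] = cds
        out["UTR"][seq_id] = utr
        out["intron"][seq_id] = intron
        out["intergenic"][seq_id] = intergenic
    return RegionSet(intervals=out, genome_lengths=dict(genome_lengths))


def classify_ssr(locus: SSRLocus, regions: RegionSet) -> str:
    """Label with the maximum base-overlap; ties CDS > UTR > intron > intergenic."""
    s0, e0 = locus.start - 1, locus.end
    best_label, best_bp = "intergenic", -1
    for label in REGION_LABELS:  # priority order breaks ties
        bp = regions.overlap_bp(label, locus.seq_id, s0, e0)
        if bp > best_bp:
            best_label, best_bp = label, bp
    return best_label


def summarize_regions(
    loci: list[SSRLocus], regions: RegionSet
) -> pd.DataFrame:
    """Quantity, SSR bp and density (bp/Mbp) per region label.

    The returned frame has one row per label plus a ``genome`` row whose
    density uses the whole genome length as denominator.
    """
    qty = {label: 0 for label in REGION_LABELS}
    bp = {label: 0 for label in REGION_LABELS}
    for loc in loci:
        label = classify_ssr(loc, regions)
        qty[label] += 1
        bp[label] += loc.length
    totals = regions.total_lengths
    rows = []
    for label in REGION_LABELS:
        t = totals[label]
        rows.append(
            {
                "region": label,
                "quantity": qty[label],
                "total_ssr_bp": bp[label],
                "region_bp": t,
                "density_bp_per_mbp": (bp[label] / (t / 1e6)) if t else float("nan"),
            }
        )
    g = regions.genome_length
    rows.append(
        {
            "region": "genome",
            "quantity": sum(qty.values()),
            "total_ssr_bp": sum(bp.values()),
            "region_bp": g,
            "density_bp_per_mbp": sum(bp.values()) / (g / 1e6) if g else float("nan"),
        }
    )
    return pd.DataFrame(rows).set_index("region")
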