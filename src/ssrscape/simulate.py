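"""Seeded synthetic genomes with ground truth for pipeline validation.

The generator emulates, at desk scale, the statistical structure of a
repeat-rich plant genome as the analysis assumes it: chromosomes with
genic (UTR/CDS/intron) and intergenic compartments, microsatellites
planted per compartment at controlled densities and motif mixes, and
full-length LTR retrotransposons whose two termini diverge by a controlled
per-site substitution process.  Every planted object is recorded in a
truth ledger so detection, region assignment and insertion dating can be
checked against exact expectations.

Three properties are enforced so recovery tests can demand exactness:

* the background sequence is rejection-sampled until it contains no
  qualifying repeat run of its own;
* planted loci are spaced more than the compound-merge interruption apart
  and their flanks are adjusted so the planted run is maximal exactly at
  its planted coordinates;
* LTR termini mutate by substitution only (no indels), so the aligner
  recovers the realized mismatch count exactly and the dating round trip
  is deterministic given the ledger.

The package-default parameter profile mirrors the qualitative genome
organisation reported for maize: UTR > CDS > intron >> intergenic SSR
density (with tri/hexanucleotide motifs concentrated in CDS and mono/di
in UTR), gene- and SSR-rich chromosome ends, LTR-rich centres, and a
flat ~4600 bp/Mbp SSR density inside LTR elements.
"""

from __future__ import annotations

from bisect import bisect_left, insort
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .motifs import canonical_motif
from .regions import Feature
from .scan import ScanConfig, scan_sequence

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _decode(arr: np.ndarray) -> str:
    return arr.tobytes().decode("ascii")


def _encode(s: str) -> np.ndarray:
    return np.frombuffer(s.encode("ascii"), dtype=np.uint8).copy()


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic genome.

    Lengths in bp, densities in bp of SSR per Mbp of compartment, ages in
    Mya.  ``region_motifs`` maps each compartment to (motif, weight)
    choices; repeat counts are geometric above the scanner threshold.
    """

    n_chromosomes: int = 2
    chromosome_length: int = 2_500_000
    genes_per_chromosome: int = 80
    utr5_length: int = 200
    utr3_length: int = 200
    n_exons: int = 5
    exon_cds_length: int = 330
    intron_length: int = 900
    gc_background: float = 0.47
    region_density: dict = field(
        default_factory=lambda: {
            "UTR": 10_000.0, "CDS": 6_500.0, "intron": 5_000.0, "intergenic": 900.0,
        }
    )
    region_motifs: dict = field(
        default_factory=lambda: {
            "UTR": [("A", 0.3), ("AG", 0.25), ("AT", 0.25), ("C", 0.1), ("AC", 0.1)],
            "CDS": [("ACC", 0.25), ("AGG", 0.2), ("AAG", 0.2), ("CCG", 0.15),
                    ("AACCCT", 0.2)],
            "intron": [("A", 0.25), ("AT", 0.2), ("AG", 0.15), ("AAT", 0.15),
                       ("AC", 0.15), ("AAAT", 0.1)],
            "intergenic": [("A", 0.2), ("AT", 0.2), ("AC", 0.15), ("AG", 0.15),
                           ("AAT", 0.1), ("AAAT", 0.1), ("AAAAT", 0.05),
                           ("AACCCT", 0.05)],
        }
    )
    repeat_geom_p: float = 0.35
    repeat_extra_max: int = 8  # repeat count capped at threshold + this
    n_ltr: int = 40
    ltr_element_length: int = 8_000
    ltr_terminus_length: int = 700
    ltr_ages_mya: tuple = tuple(np.round(np.arange(0.05, 1.0, 0.1), 2))
    mutation_rate: float = 1.3e-8
    ltr_ssr_plan: tuple = (("AG", 8), ("AAT", 7))  # planted in every element
    telomere_fraction: float = 0.3  # outer arm fraction attracting genes/SSRs
    telomere_weight: float = 0.7    # probability mass placed in the outer arms
    centromere_fraction: float = 0.4
    centromere_weight: float = 0.8
    min_spacing: int = 110  # > default max_interruption, keeps loci unmerged

    def __post_init__(self) -> None:
        for label, d in self.region_density.items():
            if d < 0:
                raise ValueError(f"negative density for {label}")
        for a in self.ltr_ages_mya:
            if a < 0:
                raise ValueError("ages must be >= 0")
            if 2 * self.mutation_rate * a * 1e6 >= 0.75:
                raise ValueError(f"age {a} Mya implies divergence >= 0.75")


@dataclass
class SyntheticTruth:
    """Ground-truth ledger of everything the generator planted."""

    ssrs: pd.DataFrame       # one row per planted locus
    region_lengths: dict     # label -> total bp
    ltr: pd.DataFrame        # one row per element, realized divergence/age
    spec: SyntheticSpec


@dataclass
class SyntheticGenome:
    sequences: dict
    features: list
    ltr_table: pd.DataFrame
    truth: SyntheticTruth


def simulate_ltr_pair(
    terminus_length: int, age_mya: float, r: float, rng: np.random.Generator
) -> tuple[str, str, int]:
    """Simulate the two termini of one element of a given age.

    The 3' terminus is derived from the 5' one by independent per-site
    substitution with probability ``p = 2 r age 1e6`` (each terminus
    accumulates ``r x age`` substitutions per site); substituted sites
    always change base, so the returned mismatch count is the realized
    pairwise difference exactly.
    """
    p = 2.0 * r * age_mya * 1e6
    if p >= 0.75:
        raise ValueError(f"expected divergence {p:.3f} >= 0.75 is not datable")
    seq5 = rng.choice(_BASES, size=terminus_length)
    seq3, n_mut = _mutate(seq5, p, rng)
    return _decode(seq5), _decode(seq3), int(n_mut)


def _mutate(arr: np.ndarray, p: float, rng: np.random.Generator):
    out = arr.copy()
    mask = rng.random(arr.size) < p
    idx = np.flatnonzero(mask)
    if idx.size:
        # shift by 1..3 positions in base order: always a different base
        cur = np.searchsorted(_BASES, out[idx])
        out[idx] = _BASES[(cur + rng.integers(1, 4, size=idx.size)) % 4]
    return out, idx.size


class _Chromosome:
    """Mutable build state for one chromosome."""

    def __init__(self, seq_id: str, arr: np.ndarray):
        self.seq_id = seq_id
        self.arr = arr
        self.planted_starts: list[int] = []  # sorted 0-based starts
        self.planted_ends: dict[int, int] = {}

    def has_room(self, s0: int, e0: int, spacing: int) -> bool:
        i = bisect_left(self.planted_starts, s0)
        if i > 0:
            prev = self.planted_starts[i - 1]
            if s0 - self.planted_ends[prev] < spacing:
                return False
        if i < len(self.planted_starts) and self.planted_starts[i] - e0 < spacing:
            return False
        return True

    def book(self, s0: int, e0: int) -> None:
        insort(self.planted_starts, s0)
        self.planted_ends[s0] = e0


def _background(length: int, gc: float, rng: np.random.Generator,
                cfg: ScanConfig) -> np.ndarray:
    """SSR-suppressed random sequence: redraw any qualifying run."""
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    arr = rng.choice(_BASES, size=length, p=probs)
    for _ in range(60):
        loci = scan_sequence(_decode(arr), cfg)
        if not loci:
            return arr
        for loc in loci:
            s, e = loc.start - 1, loc.end
            arr[max(0, s - 2): min(length, e + 2)] = rng.choice(
                _BASES, size=min(length, e + 2) - max(0, s - 2), p=probs
            )
    raise RuntimeError("background SSR suppression did not converge")


def _biased_position(length: int, span: int, rng: np.random.Generator,
                     mode: str, spec: SyntheticSpec) -> int:
    """Draw a 0-based start with telomeric or centromeric placement bias."""
    if mode == "telomere":
        if rng.random() < spec.telomere_weight:
            arm = int(spec.telomere_fraction * length)
            if rng.random() < 0.5:
                return int(rng.integers(0, max(1, arm - span)))
            return int(rng.integers(length - arm, max(length - arm + 1, length - span)))
        return int(rng.integers(0, max(1, length - span)))
    if mode == "centromere":
        if rng.random() < spec.centromere_weight:
            half = int(spec.centromere_fraction * length / 2)
            mid = length // 2
            return int(rng.integers(mid - half, max(mid - half + 1, mid + half - span)))
        return int(rng.integers(0, max(1, length - span)))
    return int(rng.integers(0, max(1, length - span)))


def _place_spans(length: int, n: int, span: int, margin: int, mode: str,
                 spec: SyntheticSpec, rng: np.random.Generator,
                 occupied: list) -> list[tuple[int, int]]:
    """Place n non-overlapping spans with a positional bias."""
    placed: list[tuple[int, int]] = []
    attempts = 0
    while len(placed) < n:
        attempts += 1
        if attempts > 200 * n:
            raise RuntimeError("could not place spans; genome too crowded")
        s0 = _biased_position(length, span + 2 * margin, rng, mode, spec) + margin
        e0 = s0 + span
        if e0 + margin > length or s0 < margin:
            continue
        if any(s0 - margin < oe and e0 + margin > os for os, oe in occupied):
            continue
        placed.append((s0, e0))
        occupied.append((s0, e0))
    placed.sort()
    return placed


def _gene_layout(spec: SyntheticSpec, s0: int) -> dict:
    """Absolute 0-based sub-intervals of one gene starting at s0."""
    cur = s0
    utr5 = (cur, cur + spec.utr5_length); cur = utr5[1]
    cds, introns = [], []
    for i in range(spec.n_exons):
        cds.append((cur, cur + spec.exon_cds_length)); cur = cds[-1][1]
        if i < spec.n_exons - 1:
            introns.append((cur, cur + spec.intron_length)); cur = introns[-1][1]
    utr3 = (cur, cur + spec.utr3_length); cur = utr3[1]
    return {"span": (s0, cur), "UTR": [utr5, utr3], "CDS": cds, "intron": introns}


def gene_length(spec: SyntheticSpec) -> int:
    return (spec.utr5_length + spec.utr3_length
            + spec.n_exons * spec.exon_cds_length
            + (spec.n_exons - 1) * spec.intron_length)


def _draw_nrep(k: int, cfg: ScanConfig, spec: SyntheticSpec,
               rng: np.random.Generator) -> int:
    lo = cfg.min_repeats[k]
    extra = rng.geometric(spec.repeat_geom_p) - 1
    return lo + min(int(extra), spec.repeat_extra_max)


def _try_plant(chrom: _Chromosome, s0: int, motif: str, nrep: int,
               cfg: ScanConfig, rng: np.random.Generator) -> bool:
    """Write a repeat at s0 and verify it scans back exactly; else undo."""
    k, L = len(motif), len(motif) * nrep
    arr, n = chrom.arr, chrom.arr.size
    backup_lo, backup_hi = max(0, s0 - 8), min(n, s0 + L + 8)
    backup = arr[backup_lo:backup_hi].copy()
    arr[s0:s0 + L] = np.tile(_encode(motif), nrep)
    for _ in range(25):
        w0, w1 = max(0, s0 - 45), min(n, s0 + L + 45)
        found = scan_sequence(_decode(arr[w0:w1]), cfg)
        if (len(found) == 1 and found[0].start == s0 - w0 + 1
                and found[0].end == s0 - w0 + L
                and found[0].motif_class == canonical_motif(motif)):
            return True
        if s0 > 0:
            arr[max(0, s0 - 8):s0] = rng.choice(_BASES, size=min(8, s0))
        arr[s0 + L:min(n, s0 + L + 8)] = rng.choice(
            _BASES, size=min(n, s0 + L + 8) - (s0 + L))
    arr[backup_lo:backup_hi] = backup
    return False


def generate_genome(spec: SyntheticSpec, seed: int,
                    cfg: ScanConfig | None = None) -> SyntheticGenome:
    """Build a genome per *spec*; identical (spec, seed) give identical output."""
    cfg = cfg or ScanConfig()
    rng = np.random.default_rng(seed)
    L = spec.chromosome_length
    chroms: list[_Chromosome] = []
    features: list[Feature] = []
    gene_ivs = {lab: [] for lab in ("UTR", "CDS", "intron")}  # (chrom_idx, s0, e0)
    ltr_rows = []
    truth_ltr = []

    glen = gene_length(spec)
    for ci in range(spec.n_chromosomes):
        seq_id = f"chr{ci + 1}"
        chrom = _Chromosome(seq_id, _background(L, spec.gc_background, rng, cfg))
        chroms.append(chrom)
        occupied: list[tuple[int, int]] = []
        genes = _place_spans(L, spec.genes_per_chromosome, glen, 200,
                             "telomere", spec, rng, occupied)
        for gi, (gs, _) in enumerate(genes):
            lay = _gene_layout(spec, gs)
            gid = f"{seq_id}.g{gi + 1}"
            span = lay["span"]
            features.append(Feature(seq_id, "gene", span[0] + 1, span[1], f"ID={gid}"))
            features.append(Feature(seq_id, "mRNA", span[0] + 1, span[1],
                                    f"ID={gid}.t1;Parent={gid}"))
            for s, e in lay["UTR"][:1]:
                features.append(Feature(seq_id, "five_prime_UTR", s + 1, e,
                                        f"Parent={gid}.t1"))
            for s, e in lay["CDS"]:
                features.append(Feature(seq_id, "CDS", s + 1, e, f"Parent={gid}.t1"))
            for s, e in lay["UTR"][1:]:
                features.append(Feature(seq_id, "three_prime_UTR", s + 1, e,
                                        f"Parent={gid}.t1"))
            # exons: UTR5+first CDS, middle CDS, last CDS+UTR3
            exons = ([(lay["UTR"][0][0], lay["CDS"][0][1])]
                     + lay["CDS"][1:-1]
                     + [(lay["CDS"][-1][0], lay["UTR"][1][1])])
            for s, e in exons:
                features.append(Feature(seq_id, "exon", s + 1, e, f"Parent={gid}.t1"))
            for lab in gene_ivs:
                gene_ivs[lab].extend((ci, s, e) for s, e in
                                     (lay[lab] if lab != "UTR" else lay["UTR"]))

        # LTR elements in the intergenic space, centromere-biased
        n_here = spec.n_ltr // spec.n_chromosomes + (
            spec.n_ltr % spec.n_chromosomes if ci == 0 else 0)
        elements = _place_spans(L, n_here, spec.ltr_element_length, 200,
                                "centromere", spec, rng, occupied)
        tl = spec.ltr_terminus_length
        for ei, (es, ee) in enumerate(elements):
            age = spec.ltr_ages_mya[(len(truth_ltr)) % len(spec.ltr_ages_mya)]
            p = 2.0 * spec.mutation_rate * age * 1e6
            for _ in range(30):
                seq5 = chrom.arr[es:es + tl].copy()
                seq3, n_mut = _mutate(seq5, p, rng)
                chrom.arr[ee - tl:ee] = seq3
                if not scan_sequence(_decode(chrom.arr[ee - tl - 6:ee + 6]), cfg):
                    break
                chrom.arr[es:es + tl] = rng.choice(_BASES, size=tl)
            else:
                raise RuntimeError("terminus redraw did not converge")
            eid = f"{seq_id}.ltr{ei + 1}"
            ltr_rows.append({
                "element_id": eid, "seq_id": seq_id,
                "start": es + 1, "end": ee,
                "ltr5_start": es + 1, "ltr5_end": es + tl,
                "ltr3_start": ee - tl + 1, "ltr3_end": ee,
            })
            d_real = n_mut / tl
            truth_ltr.append({
                "element_id": eid, "age_mya": age, "mismatches": n_mut,
                "divergence": d_real,
                "true_age_mya": d_real / (2 * spec.mutation_rate) / 1e6,
            })

    # --- plant SSRs ------------------------------------------------------
    region_lengths = {
        "UTR": spec.n_chromosomes * spec.genes_per_chromosome
               * (spec.utr5_length + spec.utr3_length),
        "CDS": spec.n_chromosomes * spec.genes_per_chromosome
               * spec.n_exons * spec.exon_cds_length,
        "intron": spec.n_chromosomes * spec.genes_per_chromosome
                  * (spec.n_exons - 1) * spec.intron_length,
    }
    region_lengths["intergenic"] = (spec.n_chromosomes * L
                                    - sum(region_lengths.values()))
    truth_ssrs: list[dict] = []

    def plant(chrom: _Chromosome, s0: int, motif: str, nrep: int,
              region: str, element_id: str = "") -> int:
        Lm = len(motif) * nrep
        if not chrom.has_room(s0, s0 + Lm, spec.min_spacing):
            return 0
        if not _try_plant(chrom, s0, motif, nrep, cfg, rng):
            return 0
        chrom.book(s0, s0 + Lm)
        truth_ssrs.append({
            "seq_id": chrom.seq_id, "start": s0 + 1, "end": s0 + Lm,
            "motif": motif, "canonical": canonical_motif(motif).canonical,
            "n_repeats": nrep, "region": region, "element_id": element_id,
        })
        return Lm

    # fixed complement inside every element: flat density across ages
    plan_len = sum(len(m) * n for m, n in spec.ltr_ssr_plan)
    ltr_bp_planted = 0
    for row in ltr_rows:
        chrom = chroms[int(row["seq_id"][3:]) - 1]
        inner_lo = row["start"] - 1 + spec.ltr_terminus_length + 30
        inner_hi = row["end"] - spec.ltr_terminus_length - 30
        cursor = inner_lo + int(rng.integers(0, 200))
        for motif, nrep in spec.ltr_ssr_plan:
            Lm = len(motif) * nrep
            for _ in range(80):
                if cursor + Lm > inner_hi:
                    cursor = inner_lo
                got = plant(chrom, cursor, motif, nrep, "intergenic",
                            row["element_id"])
                if got:
                    ltr_bp_planted += got
                    cursor += Lm + spec.min_spacing + int(rng.integers(0, 50))
                    break
                cursor += spec.min_spacing
            else:
                raise RuntimeError("could not plant in-LTR SSR")
    if plan_len * len(ltr_rows) != ltr_bp_planted:
        raise RuntimeError("in-LTR planting incomplete")

    ltr_spans = {ci: [] for ci in range(spec.n_chromosomes)}
    for row in ltr_rows:
        ltr_spans[int(row["seq_id"][3:]) - 1].append((row["start"] - 1, row["end"]))

    def plant_region(label: str, target_bp: float, already: int = 0) -> None:
        motifs, weights = zip(*spec.region_motifs[label])
        w = np.array(weights, float); w /= w.sum()
        planted = already
        slots = gene_ivs.get(label)
        misses = 0
        while planted < target_bp:
            if misses > 20000:
                raise RuntimeError(f"cannot reach density target in {label}")
            motif = motifs[int(rng.choice(len(motifs), p=w))]
            nrep = _draw_nrep(len(motif), cfg, spec, rng)
            Lm = len(motif) * nrep
            if label == "intergenic":
                ci = int(rng.integers(0, spec.n_chromosomes))
                s0 = _biased_position(L, Lm, rng, "telomere", spec)
                e0 = s0 + Lm
                chrom = chroms[ci]
                in_gene = any(os - 2 < e0 and oe + 2 > s0 for _, os, oe in
                              ((0, a, b) for lab in gene_ivs
                               for (cj, a, b) in gene_ivs[lab] if cj == ci))
                in_ltr = any(a - 2 < e0 and b + 2 > s0 for a, b in ltr_spans[ci])
                if in_gene or in_ltr:
                    misses += 1
                    continue
            else:
                idx = int(rng.choice(len(slots)))
                ci, a, b = slots[idx]
                if b - a < Lm + 6:
                    misses += 1
                    continue
                s0 = a + 3 + int(rng.integers(0, b - a - Lm - 5))
                chrom = chroms[ci]
            got = plant(chrom, s0, motif, nrep, label)
            if got:
                planted += got
            else:
                misses += 1

    for label in ("UTR", "CDS", "intron", "intergenic"):
        target = spec.region_density[label] * region_lengths[label] / 1e6
        plant_region(label, target,
                     already=ltr_bp_planted if label == "intergenic" else 0)

    sequences = {c.seq_id: _decode(c.arr) for c in chroms}
    truth = SyntheticTruth(
        ssrs=pd.DataFrame(
            truth_ssrs,
            columns=["seq_id", "start", "end", "motif", "canonical",
                     "n_repeats", "region", "element_id"],
        ).sort_values(["seq_id", "start"]).reset_index(drop=True),
        region_lengths=region_lengths,
        ltr=pd.DataFrame(truth_ltr),
        spec=spec,
    )
    return SyntheticGenome(
        sequences=sequences,
        features=features,
        ltr_table=pd.DataFrame(ltr_rows),
        truth=truth,
    )
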