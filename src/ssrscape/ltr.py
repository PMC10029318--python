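"""LTR-retrotransposon insertion dating and age-binned SSR content.

The two long terminal repeats of an element are identical at insertion and
accumulate substitutions independently afterwards, so the divergence D
between the 5' and 3' terminus, divided by twice the per-site per-year
substitution rate r, estimates the insertion age:

    T = D / (2 r),      r = 1.3e-8 substitutions/site/year by default,

the rate conventionally used for maize transposable elements.  Termini are
aligned globally (Needleman-Wunsch with affine gaps); D is the p-distance
over ungapped columns, with an optional Jukes-Cantor correction.  Dated
elements are grouped into age bins (default 0.1-Mya bins over 0-1 Mya) and
the SSR loci fully contained in each element are tallied per bin.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import Align

from .scan import SSRLocus


@dataclass(frozen=True)
class DatingConfig:
    """Alignment scoring, distance model and substitution rate."""

    mutation_rate: float = 1.3e-8  # substitutions / site / year
    match: float = 2.0
    mismatch: float = -3.0
    gap_open: float = -5.0
    gap_extend: float = -2.0
    distance_model: str = "p-distance"  # or "jukes-cantor"

    def __post_init__(self) -> None:
        if self.mutation_rate <= 0:
            raise ValueError("mutation_rate must be > 0")
        if self.distance_model not in ("p-distance", "jukes-cantor"):
            raise ValueError(f"unknown distance model {self.distance_model!r}")


@dataclass
class LTRPair:
    """One dated element: terminus divergence and derived insertion age."""

    element_id: str
    seq_id: str
    start: int  # element span, 1-based inclusive
    end: int
    five_prime: tuple[int, int]
    three_prime: tuple[int, int]
    aligned_length: int = 0
    differences: int = 0
    divergence: float = 0.0
    age_years: float = 0.0

    @property
    def age_mya(self) -> float:
        return self.age_years / 1e6

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def _aligner(cfg: DatingConfig) -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = "global"
    al.match_score = cfg.match
    al.mismatch_score = cfg.mismatch
    al.open_gap_score = cfg.gap_open
    al.extend_gap_score = cfg.gap_extend
    return al


def align_termini(a: str, b: str, cfg: DatingConfig | None = None):
    """Optimal global alignment of two termini.

    Returns the first (deterministically chosen) optimal alignment as a
    pair of gapped strings.  Raises ``ValueError`` on empty input.
    """
    if not a or not b:
        raise ValueError("cannot align empty terminus sequence")
    cfg = cfg or DatingConfig()
    aln = _aligner(cfg).align(a.upper(), b.upper())[0]
    return str(aln[0]), str(aln[1])


def divergence(alignment: tuple[str, str], model: str = "p-distance") -> float:
    """Divergence D from a gapped alignment.

    p-distance = mismatched columns / ungapped columns; gap columns are
    excluded from numerator and denominator.  The Jukes-Cantor option
    applies -(3/4) ln(1 - (4/3) p) and is undefined for p >= 0.75.
    """
    ga, gb = alignment
    if len(ga) != len(gb) or not ga:
        raise ValueError("malformed alignment")
    ungapped = mismatch = 0
    for x, y in zip(ga, gb):
        if x == "-" or y == "-":
            continue
        ungapped += 1
        if x != y:
            mismatch += 1
    if ungapped == 0:
        raise ValueError("alignment has no ungapped columns")
    p = mismatch / ungapped
    if model == "p-distance":
        return p
    if model == "jukes-cantor":
        if p >= 0.75:
            raise ValueError(f"Jukes-Cantor correction undefined for p={p:.3f} >= 0.75")
        return -0.75 * math.log1p(-4.0 * p / 3.0)
    raise ValueError(f"unknown distance model {model!r}")


def count_differences(alignment: tuple[str, str]) -> tuple[int, int]:
    """(mismatched columns, ungapped columns) of a gapped alignment."""
    ga, gb = alignment
    pairs = [(x, y) for x, y in zip(ga, gb) if x != "-" and y != "-"]
    return sum(x != y for x, y in pairs), len(pairs)


def insertion_time(d: float, cfg: DatingConfig | None = None) -> float:
    """Insertion age in years, T = D / (2 r)."""
    if d < 0:
        raise ValueError("divergence must be >= 0")
    cfg = cfg or DatingConfig()
    return d / (2.0 * cfg.mutation_rate)


def date_element(
    element_id: str,
    seq_id: str,
    span: tuple[int, int],
    five_prime: tuple[int, int],
    three_prime: tuple[int, int],
    seq5: str,
    seq3: str,
    cfg: DatingConfig | None = None,
) -> LTRPair:
    """Align the two termini of one element and derive D and T."""
    cfg = cfg or DatingConfig()
    aln = align_termini(seq5, seq3, cfg)
    diff, ungapped = count_differences(aln)
    d = divergence(aln, cfg.distance_model)
    return LTRPair(
        element_id=element_id,
        seq_id=seq_id,
        start=span[0],
        end=span[1],
        five_prime=five_prime,
        three_prime=three_prime,
        aligned_length=ungapped,
        differences=diff,
        divergence=d,
        age_years=insertion_time(d, cfg),
    )


def bin_by_age(
    pairs: list[LTRPair],
    ssr_loci: list[SSRLocus],
    bin_width_mya: float = 0.1,
    max_mya: float = 1.0,
) -> pd.DataFrame:
    """Per-age-bin SSR content of dated elements.

    An SSR locus counts toward an element iff its span lies fully inside
    the element span (density denominators are LTR bp, so partial overlaps
    are excluded).  Elements older than ``max_mya`` land in an overflow
    row labelled ``overflow`` at the end.

    Columns include the three density readouts: ``count_ratio``
    (SSRs per element), ``density_bp_per_mbp`` (SSR bp per Mbp of element
    bp) and ``length_ratio`` (mean SSR length / mean element length).
    """
    if bin_width_mya <= 0 or max_mya <= 0:
        raise ValueError("bin width and max age must be > 0")
    n_bins = int(round(max_mya / bin_width_mya))
    edges = [round(i * bin_width_mya, 10) for i in range(n_bins + 1)]

    by_seq: dict[str, list[SSRLocus]] = {}
    for loc in ssr_loci:
        by_seq.setdefault(loc.seq_id, []).append(loc)

    rows = []
    for i in range(n_bins + 1):
        rows.append(
            {
                "bin_lo_mya": edges[i] if i < n_bins else max_mya,
                "bin_hi_mya": edges[i + 1] if i < n_bins else float("inf"),
                "n_ltr": 0, "n_ssr": 0, "total_ssr_bp": 0, "total_ltr_bp": 0,
                "_ssr_lens": [], "_ltr_lens": [],
            }
        )
    for pair in pairs:
        t = pair.age_mya
        idx = min(int(t / bin_width_mya), n_bins) if t < max_mya else n_bins
        row = rows[idx]
        row["n_ltr"] += 1
        row["total_ltr_bp"] += pair.length
        row["_ltr_lens"].append(pair.length)
        for loc in by_seq.get(pair.seq_id, []):
            if loc.start >= pair.start and loc.end <= pair.end:
                row["n_ssr"] += 1
                row["total_ssr_bp"] += loc.length
                row["_ssr_lens"].append(loc.length)

    out = []
    for i, row in enumerate(rows):
        ssr_lens, ltr_lens = row.pop("_ssr_lens"), row.pop("_ltr_lens")
        row["mean_ssr_len"] = float(np.mean(ssr_lens)) if ssr_lens else float("nan")
        row["mean_ltr_len"] = float(np.mean(ltr_lens)) if ltr_lens else float("nan")
        row["count_ratio"] = row["n_ssr"] / row["n_ltr"] if row["n_ltr"] else float("nan")
        row["density_bp_per_mbp"] = (
            row["total_ssr_bp"] / (row["total_ltr_bp"] / 1e6)
            if row["total_ltr_bp"] else float("nan")
        )
        row["length_ratio"] = row["mean_ssr_len"] / row["mean_ltr_len"]
        row["bin"] = (
            f"{row['bin_lo_mya']:.1f}-{row['bin_hi_mya']:.1f}"
            if i < n_bins else "overflow"
        )
        out.append(row)
    df = pd.DataFrame(out).set_index("bin")
    return df


def log_fit(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Least-squares coefficients (a, b) of y = -b ln(x) + a.

    Used for the quantity-versus-age trend across bin midpoints.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.any(x <= 0):
        raise ValueError("x must be positive for a log fit")
    slope, intercept = np.polyfit(np.log(x), y, 1)
    return float(intercept), float(-slope)
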