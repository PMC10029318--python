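"""Independent brute-force oracles used by the test suite.

These are deliberately naive re-derivations (direct enumeration, full
dynamic-programming matrices, per-base labelling) kept separate from the
package so that scanner, aligner and region results can be checked against
an implementation that shares no code with them.
"""

from __future__ import annotations

import numpy as np

_VALID = set("ACGT")


def _primitive(unit: str) -> bool:
    n = len(unit)
    return not any(
        n % d == 0 and unit == unit[:d] * (n // d) for d in range(1, n // 2 + 1)
    )


def brute_force_runs(seq: str, min_repeats: dict[int, int]):
    """Every maximal qualifying tandem run, by testing each (start, k) pair.

    A run is anchored at the leftmost base of its periodic region (the
    period cannot be extended left by one base) and counts whole units
    only, so each maximal region is reported exactly once.
    Returns sorted tuples (start_1based, end_1based, unit, n_units).
    """
    seq = seq.upper()
    n = len(seq)
    out = []
    for k in min_repeats:
        for s in range(0, n - k + 1):
            unit = seq[s:s + k]
            if not _VALID.issuperset(unit) or not _primitive(unit):
                continue
            m = 1
            while seq[s + m * k:s + (m + 1) * k] == unit:
                m += 1
            if m < min_repeats[k]:
                continue
            if s >= 1 and seq[s - 1] in _VALID and seq[s - 1] == seq[s - 1 + k]:
                continue  # periodic region extends left: not the anchor
            out.append((s + 1, s + m * k, unit, m))
    return sorted(out)


def random_repeat_rich_sequence(rng: np.random.Generator, max_len: int = 1000) -> str:
    """Random sequence enriched for tandem runs (plus occasional N)."""
    parts = []
    length = int(rng.integers(50, max_len))
    while sum(len(p) for p in parts) < length:
        r = rng.random()
        if r < 0.45:
            parts.append("".join(rng.choice(list("ACGT"), size=int(rng.integers(5, 40)))))
        elif r < 0.9:
            k = int(rng.integers(1, 7))
            unit = "".join(rng.choice(list("ACGT"), size=k))
            parts.append(unit * int(rng.integers(2, 14)))
        else:
            parts.append("N" * int(rng.integers(1, 3)))
    return "".join(parts)[:length]


def gotoh_score(a: str, b: str, match: float, mismatch: float,
                gap_open: float, gap_extend: float) -> float:
    """Optimal global affine-gap alignment score by full-matrix DP.

    ``gap_open`` is the score of the first gapped position and
    ``gap_extend`` of each subsequent one (a length-L gap scores
    open + (L-1) * extend).
    """
    n, m = len(a), len(b)
    neg = float("-inf")
    M = np.full((n + 1, m + 1), neg)
    X = np.full((n + 1, m + 1), neg)  # gap in b (consuming a)
    Y = np.full((n + 1, m + 1), neg)  # gap in a (consuming b)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = gap_open + (i - 1) * gap_extend
    for j in range(1, m + 1):
        Y[0, j] = gap_open + (j - 1) * gap_extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            M[i, j] = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]) + s
            X[i, j] = max(M[i - 1, j] + gap_open, X[i - 1, j] + gap_extend,
                          Y[i - 1, j] + gap_open)
            Y[i, j] = max(M[i, j - 1] + gap_open, X[i, j - 1] + gap_open,
                          Y[i, j - 1] + gap_extend)
    return float(max(M[n, m], X[n, m], Y[n, m]))


def per_base_region_labels(features, length: int) -> list[str]:
    """Label every base of one sequence by direct painting with priority.

    Paint intergenic, then gene spans as intron, then UTR, then CDS — the
    final colour of each base is the highest-priority label covering it.
    UTR bases come from explicit UTR records when present, else from
    exon-minus-CDS.
    """
    lab = ["intergenic"] * length
    has_utr = any("utr" in f.kind.lower() for f in features)
    for f in features:
        if f.kind.lower() in ("gene", "mrna", "transcript"):
            for i in range(f.start - 1, f.end):
                lab[i] = "intron"
    if has_utr:
        for f in features:
            if "utr" in f.kind.lower():
                for i in range(f.start - 1, f.end):
                    lab[i] = "UTR"
    else:
        cds_mask = [False] * length
        for f in features:
            if f.kind.lower() == "cds":
                for i in range(f.start - 1, f.end):
                    cds_mask[i] = True
        for f in features:
            if f.kind.lower() == "exon":
                for i in range(f.start - 1, f.end):
                    if not cds_mask[i]:
                        lab[i] = "UTR"
    for f in features:
        if f.kind.lower() == "cds":
            for i in range(f.start - 1, f.end):
                lab[i] = "CDS"
    return lab
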