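"""Fixed-width chromosome density tracks (the data layer behind Circos plots).

Each sequence is tiled with windows of a fixed width (default 1 Mb; the
last window may be short).  For each track (SSR, gene, LTR-RT, ...) the
occupied bp per window is the exact interval/window intersection, so a
feature straddling a boundary contributes to each window proportionally to
its overlap and track totals are conserved under any window width.
"""

from __future__ import annotations

import pandas as pd

from . import intervals as iv


def windowed_density(
    tracks: dict[str, dict[str, list[tuple[int, int]]]],
    genome_lengths: dict[str, int],
    width: int = 1_000_000,
) -> pd.DataFrame:
    """Per-window occupied bp and fraction for each track.

    Parameters
    ----------
    tracks
        ``{track_name: {seq_id: [(start0, end0), ...]}}`` with 0-based
        half-open intervals (need not be sorted or disjoint; overlaps are
        flattened so occupied bp never exceeds the window).
    genome_lengths
        Length of every sequence to tile.
    width
        Window width in bp; must be positive.

    Returns
    -------
    DataFrame with one row per (seq_id, window): columns ``start``/``end``
    (1-based inclusive) plus ``<track>_bp`` and ``<track>_frac``.
    """
    if width <= 0:
        raise ValueError("window width must be > 0")
    names = list(tracks)
    merged = {
        name: {sid: iv.merge([(max(0, s), min(e, genome_lengths.get(sid, e)))
                              for s, e in ivs])
               for sid, ivs in per_seq.items() if sid in genome_lengths}
        for name, per_seq in tracks.items()
    }
    rows = []
    for sid, length in genome_lengths.items():
        pointers = {name: 0 for name in names}
        for w0 in range(0, length, width):
            w1 = min(w0 + width, length)
            row = {"seq_id": sid, "start": w0 + 1, "end": w1}
            for name in names:
                ivs = merged[name].get(sid, [])
                j = pointers[name]
                while j < len(ivs) and ivs[j][1] <= w0:
                    j += 1
                pointers[name] = j
                bp = 0
                k = j
                while k < len(ivs) and ivs[k][0] < w1:
                    s, e = ivs[k]
                    bp += min(e, w1) - max(s, w0)
                    k += 1
                row[f"{name}_bp"] = bp
                row[f"{name}_frac"] = bp / (w1 - w0)
            rows.append(row)
    return pd.DataFrame(rows)
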