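"""Cross-genome summary statistics: AVG/CV tables and length quartiles.

The multi-genome survey convention is a table with one row per genome and
one column per motif size (or region), closed by an AVG row (arithmetic
mean) and a CV row (coefficient of variation, 100 x sample SD / mean,
sample meaning the n-1 denominator).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: SSR counts per motif size reported for five public maize inbred genomes
#: (B73, W22, SK, PE0075, LT2357) in a genome-wide microsatellite survey;
#: used as reference input for cross-genome statistics.
MAIZE_SSR_COUNTS = pd.DataFrame(
    {
        "MNR": [74612, 63503, 78951, 71105, 81236],
        "DNR": [41595, 43239, 41952, 41531, 43039],
        "TNR": [16223, 15279, 16330, 16874, 18879],
        "TTR": [3484, 3389, 3464, 3404, 3385],
        "PNR": [5259, 4861, 5334, 5286, 5311],
        "HNR": [3222, 2602, 3835, 3168, 3427],
        "Total": [144395, 132873, 149866, 141368, 155277],
    },
    index=["B73", "W22", "SK", "PE0075", "LT2357"],
)

#: GC content (%) of the six motif sizes in the same five genomes.
MAIZE_SSR_GC = pd.DataFrame(
    {
        "Mononucleotide": [64.10, 55.87, 65.15, 60.42, 62.72],
        "Dinucleotide": [19.36, 17.18, 19.46, 18.92, 19.59],
        "Trinucleotide": [46.48, 46.27, 46.57, 46.17, 42.09],
        "Tetranucleotide": [36.53, 37.33, 38.07, 37.66, 36.23],
        "Pentanucleotide": [53.50, 54.98, 54.26, 53.17, 53.70],
        "Hexanucleotide": [55.68, 56.95, 55.53, 56.04, 55.43],
    },
    index=["B73", "W22", "SK", "PE0075", "LT2357"],
)


def cv_stat(values) -> float:
    """Coefficient of variation, percent: 100 x sample SD (n-1) / mean.

    Requires at least two values and a non-zero mean; reported to 2
    decimals in tables.
    """
    a = np.asarray(list(values), dtype=float)
    if a.size < 2:
        raise ValueError("CV requires at least two values")
    m = a.mean()
    if m == 0:
        raise ValueError("CV undefined for zero mean")
    return float(100.0 * a.std(ddof=1) / m)


def quartile_summary(lengths) -> dict[str, float]:
    """Median, Q1 and Q3 by the linear-interpolation convention."""
    a = np.asarray(list(lengths), dtype=float)
    if a.size == 0:
        raise ValueError("empty length list")
    q1, med, q3 = np.percentile(a, [25, 50, 75])
    return {"median": float(med), "Q1": float(q1), "Q3": float(q3)}


def cross_genome_table(table: pd.DataFrame, decimals: int | None = None) -> pd.DataFrame:
    """Append AVG and CV (%) rows to a genomes-by-columns table.

    ``decimals=0`` rounds AVG to integers (count tables); ``decimals=2``
    is the percentage-table convention; CV is always 2 decimals.
    """
    avg = table.mean(axis=0)
    cv = table.apply(cv_stat, axis=0)
    if decimals == 0:
        avg = avg.round().astype(int)
    elif decimals is not None:
        avg = avg.round(decimals)
    out = table.copy()
    out.loc["AVG"] = avg
    out.loc["CV (%)"] = cv.round(2)
    return out
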