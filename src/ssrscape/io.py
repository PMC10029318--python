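"""Readers and writers for the standard formats the pipeline consumes.

FASTA via Biopython (gzip-transparent); GFF3/GTF via a small column
parser that extracts the interval features the region layer needs; SSR
and LTR tables as TSV with explicit headers.  All coordinates in emitted
files are 1-based inclusive.
"""

from __future__ import annotations

import gzip
import json
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .motifs import canonical_motif
from .regions import Feature
from .scan import SSRLocus

SSR_COLUMNS = [
    "seq_id", "start", "end", "motif", "canonical_class",
    "unit_size", "n_repeats", "length", "kind",
]


def _open_text(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def read_fasta(path) -> dict[str, str]:
    """Ordered {id: uppercase sequence}; IDs are the first token.

    Raises on an empty file or duplicate IDs.
    """
    out: dict[str, str] = {}
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            if rec.id in out:
                raise ValueError(f"duplicate FASTA id {rec.id!r}")
            out[rec.id] = str(rec.seq).upper()
    if not out:
        raise ValueError(f"no FASTA records in {path}")
    return out


def write_fasta(sequences: dict[str, str], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for sid, seq in sequences.items():
            fh.write(f">{sid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_gff3(path, dialect: str = "gff3") -> list[Feature]:
    """Interval features from GFF3 (or GTF with ``dialect='gtf'``).

    Only the columns the region partition needs are kept: seq_id, type,
    start, end, attributes.
    """
    feats: list[Feature] = []
    with _open_text(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9:
                raise ValueError(f"malformed {dialect} line: {line[:80]!r}")
            seq_id, _src, kind, start, end = parts[0], parts[1], parts[2], parts[3], parts[4]
            feats.append(Feature(seq_id, kind, int(start), int(end), parts[8]))
    return feats


def write_gff3(features: list[Feature], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            fh.write(f"{f.seq_id}\tssrscape\t{f.kind}\t{f.start}\t{f.end}"
                     f"\t.\t+\t.\t{f.attributes or '.'}\n")


def loci_to_frame(loci: list[SSRLocus]) -> pd.DataFrame:
    rows = [
        {
            "seq_id": l.seq_id, "start": l.start, "end": l.end, "motif": l.motif,
            "canonical_class": l.motif_class.canonical, "unit_size": l.unit_size,
            "n_repeats": l.n_repeats, "length": l.length, "kind": l.kind,
        }
        for l in loci
    ]
    return pd.DataFrame(rows, columns=SSR_COLUMNS)


def write_ssr_tsv(loci: list[SSRLocus], path) -> None:
    loci_to_frame(loci).to_csv(path, sep="\t", index=False)


def read_ssr_tsv(path) -> list[SSRLocus]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for row in df.itertuples():
        out.append(
            SSRLocus(
                seq_id=str(row.seq_id), start=int(row.start), end=int(row.end),
                motif=str(row.motif),
                motif_class=canonical_motif(str(row.motif)),
                n_repeats=int(row.n_repeats), kind=str(row.kind),
            )
        )
    return out


def write_misa_tsv(loci: list[SSRLocus], path) -> None:
    """MISA-style output dialect (ID, SSR nr., type, SSR, size, start, end)."""
    with open(path, "w") as fh:
        fh.write("ID\tSSR nr.\tSSR type\tSSR\tsize\tstart\tend\n")
        counters: dict[str, int] = {}
        for l in loci:
            n = counters.get(l.seq_id, 0) + 1
            counters[l.seq_id] = n
            if l.kind == "compound":
                ssr = "*".join(f"({s.motif}){s.n_repeats}" for s in l.sub_loci)
                typ = "c"
            else:
                ssr = f"({l.motif}){l.n_repeats}"
                typ = f"p{l.unit_size}"
            fh.write(f"{l.seq_id}\t{n}\t{typ}\t{ssr}\t{l.length}\t{l.start}\t{l.end}\n")


LTR_COLUMNS = ["element_id", "seq_id", "start", "end",
               "ltr5_start", "ltr5_end", "ltr3_start", "ltr3_end"]


def read_ltr_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(LTR_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"LTR table missing columns: {sorted(missing)}")
    return df


def write_ltr_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, columns=LTR_COLUMNS)


def write_manifest(path, **entries) -> None:
    with open(path, "w") as fh:
        json.dump(entries, fh, indent=2, default=str)
        fh.write("\n")
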