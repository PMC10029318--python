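"""End-to-end orchestration: scan -> regions -> windows -> LTR dating -> summary."""

from __future__ import annotations

import hashlib
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import io as sio
from .ltr import DatingConfig, bin_by_age, date_element
from .regions import build_region_set, classify_ssr, summarize_regions
from .scan import ScanConfig, scan_genome
from .stats import gc_content, length_class_histogram
from .windows import windowed_density

log = logging.getLogger("ssrscape")


class StageError(RuntimeError):
    def __init__(self, stage: str, code: str, message: str):
        super().__init__(f"[{stage}:{code}] {message}")
        self.stage, self.code = stage, code


@dataclass
class PipelineConfig:
    fasta: Path
    gff: Path | None = None
    ltr: Path | None = None
    outdir: Path = Path("ssrscape_out")
    scan: ScanConfig = field(default_factory=ScanConfig)
    dating: DatingConfig = field(default_factory=DatingConfig)
    window_width: int = 1_000_000
    bin_width_mya: float = 0.1
    max_age_mya: float = 1.0
    gff_dialect: str = "gff3"


def _checksum(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage, write TSVs plus a manifest, return the tables.

    The LTR stage is skipped (and flagged in the manifest) when no element
    table is given.  Output is deterministic for fixed inputs and config.
    """
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict = {}
    manifest: dict = {"parameters": {
        "min_repeats": cfg.scan.min_repeats,
        "max_interruption": cfg.scan.max_interruption,
        "mutation_rate": cfg.dating.mutation_rate,
        "distance_model": cfg.dating.distance_model,
        "window_width": cfg.window_width,
        "coordinate_convention": "1-based inclusive in all emitted tables",
    }, "inputs": {}, "stages": {}}

    def stage(name):
        def deco(fn):
            t0 = time.perf_counter()
            try:
                fn()
            except StageError:
                raise
            except Exception as e:  # noqa: BLE001
                raise StageError(name, "failed", str(e)) from e
            dt = time.perf_counter() - t0
            manifest["stages"][name] = {"status": "ok", "seconds": round(dt, 2)}
            log.info("stage %s done in %.2fs", name, dt)
        return deco

    sequences: dict = {}

    @stage("scan")
    def _scan():
        nonlocal sequences
        sequences = sio.read_fasta(cfg.fasta)
        manifest["inputs"]["fasta"] = {"path": str(cfg.fasta),
                                       "sha256_16": _checksum(cfg.fasta)}
        bundle["loci"] = scan_genome(sequences, cfg.scan)
        sio.write_ssr_tsv(bundle["loci"], out / "ssr.tsv")
        bundle["gc"] = gc_content(bundle["loci"])
        bundle["length_hist"] = length_class_histogram(bundle["loci"])
        bundle["length_hist"].to_csv(out / "length_histogram.tsv", sep="\t")

    genome_lengths = {}

    @stage("regions")
    def _regions():
        nonlocal genome_lengths
        genome_lengths = {sid: len(s) for sid, s in sequences.items()}
        if cfg.gff is None:
            features = []
        else:
            features = sio.read_gff3(cfg.gff, cfg.gff_dialect)
            manifest["inputs"]["gff"] = {"path": str(cfg.gff),
                                         "sha256_16": _checksum(cfg.gff)}
        regions = build_region_set(features, genome_lengths)
        bundle["regions"] = regions
        bundle["region_summary"] = summarize_regions(bundle["loci"], regions)
        bundle["region_summary"].to_csv(out / "region_summary.tsv", sep="\t")
        df = sio.loci_to_frame(bundle["loci"])
        df["region"] = [classify_ssr(l, regions) for l in bundle["loci"]]
        df.to_csv(out / "ssr_with_regions.tsv", sep="\t", index=False)
        bundle["features"] = features

    @stage("windows")
    def _windows():
        regions = bundle["regions"]
        genic = {
            sid: [iv for lab in ("CDS", "UTR", "intron")
                  for iv in regions.intervals[lab].get(sid, [])]
            for sid in genome_lengths
        }
        ssr = {}
        for l in bundle["loci"]:
            ssr.setdefault(l.seq_id, []).append((l.start - 1, l.end))
        tracks = {"ssr": ssr, "gene": genic}
        if cfg.ltr is not None:
            ltr_df = sio.read_ltr_table(cfg.ltr)
            tracks["ltr"] = {
                sid: [(int(r.start) - 1, int(r.end))
                      for r in ltr_df.itertuples() if r.seq_id == sid]
                for sid in genome_lengths
            }
        bundle["windows"] = windowed_density(tracks, genome_lengths, cfg.window_width)
        bundle["windows"].to_csv(out / "window_tracks.tsv", sep="\t", index=False)

    if cfg.ltr is None:
        manifest["stages"]["ltr_age"] = {"status": "skipped",
                                         "reason": "no LTR element table supplied"}
    else:
        @stage("ltr_age")
        def _ltr():
            ltr_df = sio.read_ltr_table(cfg.ltr)
            manifest["inputs"]["ltr"] = {"path": str(cfg.ltr),
                                         "sha256_16": _checksum(cfg.ltr)}
            pairs = []
            for r in ltr_df.itertuples():
                seq = sequences[str(r.seq_id)]
                seq5 = seq[int(r.ltr5_start) - 1:int(r.ltr5_end)]
                seq3 = seq[int(r.ltr3_start) - 1:int(r.ltr3_end)]
                pairs.append(date_element(
                    str(r.element_id), str(r.seq_id),
                    (int(r.start), int(r.end)),
                    (int(r.ltr5_start), int(r.ltr5_end)),
                    (int(r.ltr3_start), int(r.ltr3_end)),
                    seq5, seq3, cfg.dating,
                ))
            bundle["ltr_pairs"] = pairs
            per_el = pd.DataFrame([
                {"element_id": p.element_id, "seq_id": p.seq_id,
                 "start": p.start, "end": p.end,
                 "aligned_length": p.aligned_length, "differences": p.differences,
                 "divergence": round(p.divergence, 6),
                 "age_mya": round(p.age_mya, 3)}
                for p in pairs
            ])
            per_el.to_csv(out / "ltr_ages.tsv", sep="\t", index=False)
            bundle["age_bins"] = bin_by_age(pairs, bundle["loci"],
                                            cfg.bin_width_mya, cfg.max_age_mya)
            bundle["age_bins"].to_csv(out / "ltr_age_bins.tsv", sep="\t")

    sio.write_manifest(out / "manifest.json", **manifest)
    bundle["manifest"] = manifest
    return bundle
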