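"""Streaming allele counting: FASTQ -> per-(plate, well, gene, allele) counts.

One pass over the reads; each read contributes at most one count.  The
bookkeeping preserves the partition property

    reads_seen = reads_assigned + reads_unassigned (+ reads_quality_filtered)
    reads_classified + reads_ambiguous + reads_unclassified = reads_assigned

which holds on every run and is asserted by :meth:`DemuxTotals.check`.
"""

from __future__ import annotations

import gzip
import json
import logging
from collections import Counter
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .barcodes import UNASSIGNED, BarcodeIndex, BarcodeManifest, demultiplex_read
from .panel import AMBIGUOUS, UNCLASSIFIED, AmpliconPanel, classify_allele

logger = logging.getLogger(__name__)


class FastqError(ValueError):
    pass


@dataclass
class ReadAssignment:
    """Full disposition of one read (plumbing for oracles and debugging)."""

    read_id: str
    plate_id: str  # or UNASSIGNED
    well_id: str  # or UNASSIGNED
    gene: str | None
    allele_id: str | None  # concrete id, AMBIGUOUS, or UNCLASSIFIED; None if unassigned


@dataclass
class DemuxTotals:
    reads_seen: int = 0
    reads_assigned: int = 0
    reads_unassigned: int = 0
    reads_quality_filtered: int = 0
    reads_classified: int = 0
    reads_ambiguous: int = 0
    reads_unclassified: int = 0

    def check(self) -> None:
        assert (
            self.reads_seen
            == self.reads_assigned + self.reads_unassigned + self.reads_quality_filtered
        ), "partition violated: seen != assigned + unassigned + filtered"
        assert (
            self.reads_assigned
            == self.reads_classified + self.reads_ambiguous + self.reads_unclassified
        ), "partition violated: assigned != classified + ambiguous + unclassified"


@dataclass
class AlleleCountMatrix:
    """Counts keyed by (plate_id, well_id, gene, allele_id) plus run totals."""

    counts: Counter = field(default_factory=Counter)
    totals: DemuxTotals = field(default_factory=DemuxTotals)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"plate_id": p, "well_id": w, "gene": g, "allele_id": a, "count": n}
            for (p, w, g, a), n in sorted(self.counts.items())
        ]
        return pd.DataFrame(rows, columns=["plate_id", "well_id", "gene", "allele_id", "count"])

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "AlleleCountMatrix":
        df = pd.read_csv(path, sep="\t", dtype={"count": int}, keep_default_na=False)
        mat = cls()
        for row in df.itertuples(index=False):
            if row.count < 0:
                raise ValueError(f"{path}: negative count for {row.plate_id}/{row.well_id}")
            mat.counts[(row.plate_id, row.well_id, row.gene, row.allele_id)] = int(row.count)
        return mat

    def summary(self) -> dict:
        t = self.totals
        return {
            "totals": asdict(t),
            "unassigned_rate": (t.reads_unassigned / t.reads_seen) if t.reads_seen else 0.0,
            "classified_rate": (t.reads_classified / t.reads_seen) if t.reads_seen else 0.0,
            "n_wells_with_counts": len({(p, w) for (p, w, _, _) in self.counts}),
        }

    def write_summary(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.summary(), fh, indent=2)


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def iter_fastq(path: str | Path) -> Iterator[tuple[str, str, str]]:
    """Yield (read_id, sequence, quality); raise FastqError with the record
    index on a truncated/malformed record."""
    n = 0
    with _open_text(path) as fh:
        it = FastqGeneralIterator(fh)
        while True:
            try:
                title, seq, qual = next(it)
            except StopIteration:
                return
            except ValueError as exc:
                raise FastqError(f"{path}: malformed FASTQ at record {n}: {exc}") from exc
            n += 1
            yield title.split()[0], seq, qual


def _mean_quality(qual: str) -> float:
    return sum(ord(c) - 33 for c in qual) / len(qual) if qual else 0.0


def assign_read(
    read_id: str,
    seq: str,
    manifest: BarcodeManifest,
    panel: AmpliconPanel,
) -> ReadAssignment:
    """Single-read reference path: demultiplex both barcodes, then classify.

    Allele classification is reported only for fully assigned reads, mirroring
    the streaming counter.
    """
    plate, well = demultiplex_read(seq, manifest)
    if plate == UNASSIGNED or well == UNASSIGNED:
        return ReadAssignment(read_id, plate, well, None, None)
    gene, allele = classify_allele(seq, panel)
    return ReadAssignment(read_id, plate, well, gene, allele)


def count_pool(
    fastq: str | Path | Iterable[tuple[str, str, str]],
    manifest: BarcodeManifest,
    panel: AmpliconPanel,
    platemap: pd.DataFrame | None = None,
    min_mean_quality: float | None = None,
) -> AlleleCountMatrix:
    """Stream reads and accumulate allele counts per well.

    ``fastq`` may be a path (``.gz`` supported) or an iterable of
    ``(read_id, seq, qual)`` tuples.  When a plate map is given, reads
    assigned to (plate, well) pairs absent from the map are still counted but
    reported in the log; downstream scoring is driven by the map.
    Ambiguous and unclassified reads are never counted toward any allele.
    """
    reads = iter_fastq(fastq) if isinstance(fastq, (str, Path)) else iter(fastq)
    index = BarcodeIndex(manifest)
    mat = AlleleCountMatrix()
    t = mat.totals
    counts = mat.counts
    known_wells = (
        {(p, w) for p, w in zip(platemap["plate_id"], platemap["well_id"])}
        if platemap is not None
        else None
    )
    unmapped = 0
    for read_id, seq, qual in reads:
        t.reads_seen += 1
        if min_mean_quality is not None and _mean_quality(qual) < min_mean_quality:
            t.reads_quality_filtered += 1
            continue
        seq = seq.upper()
        plate, well = index.assign(seq)
        if plate == UNASSIGNED or well == UNASSIGNED:
            t.reads_unassigned += 1
            continue
        t.reads_assigned += 1
        if known_wells is not None and (plate, well) not in known_wells:
            unmapped += 1
        gene, allele = classify_allele(seq, panel)
        if allele == AMBIGUOUS:
            t.reads_ambiguous += 1
        elif allele == UNCLASSIFIED:
            t.reads_unclassified += 1
        else:
            t.reads_classified += 1
            counts[(plate, well, gene, allele)] += 1
    t.check()
    if unmapped:
        logger.warning("%d reads assigned to wells absent from the plate map", unmapped)
    per_well = Counter()
    for (p, w, _, _), n in counts.items():
        per_well[(p, w)] += n
    for (p, w), n in sorted(per_well.items()):
        logger.debug("well %s/%s: %d classified reads", p, w, n)
    logger.info(
        "count_pool: %d reads seen, %d assigned (%.2f%%), %d classified",
        t.reads_seen,
        t.reads_assigned,
        100.0 * t.reads_assigned / t.reads_seen if t.reads_seen else 0.0,
        t.reads_classified,
    )
    return mat
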