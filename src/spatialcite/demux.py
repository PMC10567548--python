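"""Spatial-barcode demultiplexing: Read 2 -> pixel address.

Each read pair is assigned the pixel AiBj whose barcodes its Read 2
carries. Gates are applied in a fixed order with first-failure accounting
so the stats decompose exactly: (0) structural length check, (1) linker
Hamming gate, (2) barcode A correction, (3) barcode B correction. A
barcode within the correction radius of two whitelist entries at the same
minimal distance is *ambiguous* and the read is dropped — never resolved
arbitrarily, since a wrong pixel is spatial cross-contamination.

When the whitelist's minimum pairwise Hamming distance d_min satisfies
2*max_hamming < d_min, a read whose barcode carries at most max_hamming
substitutions can never be corrected to the wrong entry (the true entry is
strictly nearest); this is the radius-safety condition checked at load.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

from spatialcite.barcodes import BarcodeWhitelist, hamming
from spatialcite.errors import DataError
from spatialcite.fastq import read_fastq_pairs
from spatialcite.layout import ReadLayout
from spatialcite.matrix import PixelAddress

AMBIGUOUS = "ambiguous"
NO_MATCH = "no_match"
MATCHED = "matched"


@dataclass(frozen=True)
class RawBarcodeCall:
    """Read-2 components sliced by layout, before any correction."""

    umi_seq: str
    bcB_seq: str
    linker_seq: str
    bcA_seq: str


@dataclass(frozen=True)
class DemuxRecord:
    read_id: str
    pixel: PixelAddress
    umi_seq: str
    payload_seq: str
    modality: str


@dataclass
class DemuxStats:
    """Per-library gate accounting; every read is counted exactly once at
    its first failing gate, so the categories sum to the total."""

    total_reads: int = 0
    short_read: int = 0
    fail_linker: int = 0
    fail_bcA: int = 0
    fail_bcB: int = 0
    ambiguous: int = 0
    passed: int = 0

    def conserved(self) -> bool:
        return self.total_reads == (
            self.short_read
            + self.fail_linker
            + self.fail_bcA
            + self.fail_bcB
            + self.ambiguous
            + self.passed
        )

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def parse_read2(seq: str, layout: ReadLayout) -> RawBarcodeCall:
    """Slice Read 2 into its components by layout offsets (no correction).

    Raises
    ------
    DataError
        If the read is shorter than the layout span (demux_library counts
        this as a structural `short_read` failure instead of raising).
    """
    if len(seq) < layout.span:
        raise DataError(
            f"read length {len(seq)} shorter than layout span {layout.span}"
        )
    return RawBarcodeCall(
        umi_seq=layout.umi.slice(seq),
        bcB_seq=layout.bcB.slice(seq),
        linker_seq=layout.linker.slice(seq),
        bcA_seq=layout.bcA.slice(seq),
    )


def classify_barcode(
    seq: str, wl: BarcodeWhitelist, max_hamming: int
) -> tuple[int | None, str]:
    """Correct `seq` against the whitelist; returns (index, status).

    Exact matches always win. Otherwise the unique entry at the minimal
    Hamming distance <= max_hamming is returned; a tie at that minimal
    distance is (None, "ambiguous"); nothing within the radius is
    (None, "no_match").
    """
    if len(seq) != wl.barcode_length:
        raise DataError(
            f"barcode length {len(seq)} != whitelist length {wl.barcode_length}"
        )
    best_idx: int | None = None
    best_d = max_hamming + 1
    tied = False
    for idx, ref in wl.entries:
        d = hamming(seq, ref)
        if d == 0:
            return idx, MATCHED
        if d < best_d:
            best_idx, best_d, tied = idx, d, False
        elif d == best_d and best_d <= max_hamming:
            tied = True
    if best_d > max_hamming:
        return None, NO_MATCH
    if tied:
        return None, AMBIGUOUS
    return best_idx, MATCHED


def correct_barcode(seq: str, wl: BarcodeWhitelist, max_hamming: int) -> int | None:
    """Whitelist index for `seq`, or None (no match / ambiguous)."""
    idx, _ = classify_barcode(seq, wl, max_hamming)
    return idx


def demux_library(
    fastq_pair: tuple[str, str],
    layout: ReadLayout,
    wl_a: BarcodeWhitelist,
    wl_b: BarcodeWhitelist,
    max_hamming_bc: int = 1,
    max_hamming_linker: int = 2,
    modality: str = "RNA",
) -> tuple[Iterator[DemuxRecord], DemuxStats]:
    """Stream a paired FASTQ library into pixel-addressed records.

    Returns a lazy record iterator plus the stats object, which is complete
    only after the iterator is exhausted. Memory is bounded: precomputed
    Hamming-ball lookup tables per whitelist, one read pair in flight.
    """
    if layout.bcA.length != wl_a.barcode_length:
        raise DataError(
            f"layout bcA length {layout.bcA.length} != whitelist A "
            f"barcode length {wl_a.barcode_length}"
        )
    if layout.bcB.length != wl_b.barcode_length:
        raise DataError(
            f"layout bcB length {layout.bcB.length} != whitelist B "
            f"barcode length {wl_b.barcode_length}"
        )
    stats = DemuxStats()
    matcher_a = wl_a.build_matcher(max_hamming_bc)
    matcher_b = wl_b.build_matcher(max_hamming_bc)

    def gen() -> Iterator[DemuxRecord]:
        for read_id, r1_seq, r2_seq in read_fastq_pairs(*fastq_pair):
            stats.total_reads += 1
            if len(r2_seq) < layout.span:
                stats.short_read += 1
                continue
            call = parse_read2(r2_seq, layout)
            if hamming(call.linker_seq, layout.linker_seq) > max_hamming_linker:
                stats.fail_linker += 1
                continue
            hit_a = matcher_a.get(call.bcA_seq)
            if hit_a is None:
                stats.fail_bcA += 1
                continue
            if hit_a[0] == 0:
                stats.ambiguous += 1
                continue
            hit_b = matcher_b.get(call.bcB_seq)
            if hit_b is None:
                stats.fail_bcB += 1
                continue
            if hit_b[0] == 0:
                stats.ambiguous += 1
                continue
            stats.passed += 1
            yield DemuxRecord(
                read_id=read_id,
                pixel=PixelAddress(row=hit_a[0], col=hit_b[0]),
                umi_seq=call.umi_seq,
                payload_seq=r1_seq,
                modality=modality,
            )

    return gen(), stats
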