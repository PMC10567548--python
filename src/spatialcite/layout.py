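"""Read-2 layout: where UMI, spatial barcodes and linker sit in the read.

Barcode B contributes four functional regions to the final construct
(ligation linker, spatial barcode, UMI, PCR primer) and barcode A three
(poly(T), spatial barcode, ligation linker); after ligation, Read 2 of
both libraries reads through UMI + barcode B + linker + barcode A. Exact
lengths are panel-design choices, so the layout is fully configurable;
defaults are 10-nt UMI, 8-nt barcodes, 30-nt linker.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from spatialcite.barcodes import is_dna
from spatialcite.errors import ConfigError

DEFAULT_UMI_LENGTH = 10
DEFAULT_BARCODE_LENGTH = 8
DEFAULT_LINKER_SEQ = "GTGGCCGATGTTTCGCATCGGCGTACGACT"  # 30 nt


@dataclass(frozen=True)
class Segment:
    offset: int
    length: int

    def __post_init__(self) -> None:
        if self.offset < 0 or self.length <= 0:
            raise ConfigError(f"bad segment (offset={self.offset}, length={self.length})")

    @property
    def end(self) -> int:
        return self.offset + self.length

    def slice(self, seq: str) -> str:
        return seq[self.offset : self.end]


@dataclass(frozen=True)
class ReadLayout:
    """Byte offsets of the Read-2 components, plus the Read-1 tag region
    used by the ADT library.

    Attributes
    ----------
    umi, bcB, linker, bcA : Segment
        Non-overlapping Read-2 segments, in any order along the read.
    linker_seq : str
        Expected linker sequence (length must equal ``linker.length``).
    r1_tag : Segment
        Position of the antibody tag within Read 1 (ADT library only).
    """

    umi: Segment = Segment(0, DEFAULT_UMI_LENGTH)
    bcB: Segment = Segment(DEFAULT_UMI_LENGTH, DEFAULT_BARCODE_LENGTH)
    linker: Segment = Segment(
        DEFAULT_UMI_LENGTH + DEFAULT_BARCODE_LENGTH, len(DEFAULT_LINKER_SEQ)
    )
    bcA: Segment = Segment(
        DEFAULT_UMI_LENGTH + DEFAULT_BARCODE_LENGTH + len(DEFAULT_LINKER_SEQ),
        DEFAULT_BARCODE_LENGTH,
    )
    linker_seq: str = DEFAULT_LINKER_SEQ
    r1_tag: Segment = Segment(0, 15)
    read2_length: int = field(default=0)  # 0 -> exactly the parsed span

    def __post_init__(self) -> None:
        if len(self.linker_seq) != self.linker.length:
            raise ConfigError(
                f"linker_seq length {len(self.linker_seq)} != linker segment "
                f"length {self.linker.length}"
            )
        if not is_dna(self.linker_seq):
            raise ConfigError(f"linker_seq is not ACGT DNA: {self.linker_seq!r}")
        segs = sorted(self.read2_segments(), key=lambda s: s.offset)
        for a, b in zip(segs, segs[1:]):
            if a.end > b.offset:
                raise ConfigError(
                    f"overlapping Read-2 segments at offsets {a.offset} and {b.offset}"
                )
        if self.read2_length and self.span > self.read2_length:
            raise ConfigError(
                f"layout span {self.span} exceeds read2_length {self.read2_length}"
            )

    def read2_segments(self) -> tuple[Segment, Segment, Segment, Segment]:
        return (self.umi, self.bcB, self.linker, self.bcA)

    @property
    def span(self) -> int:
        """Minimum Read-2 length the layout can be parsed from."""
        return max(s.end for s in self.read2_segments())

    @classmethod
    def from_dict(cls, d: dict) -> "ReadLayout":
        """Build from a config mapping like
        ``{umi: [0, 10], bcB: [10, 8], linker: [18, 30], bcA: [48, 8],
        linker_seq: ..., r1_tag: [0, 15]}`` (missing keys use defaults)."""
        kwargs = {}
        for name in ("umi", "bcB", "linker", "bcA", "r1_tag"):
            if name in d:
                off, ln = d[name]
                kwargs[name] = Segment(int(off), int(ln))
        for name in ("linker_seq",):
            if name in d:
                kwargs[name] = str(d[name]).upper()
        if "read2_length" in d:
            kwargs["read2_length"] = int(d["read2_length"])
        unknown = set(d) - {"umi", "bcB", "linker", "bcA", "r1_tag", "linker_seq", "read2_length"}
        if unknown:
            raise ConfigError(f"unknown layout key(s): {sorted(unknown)}")
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return {
            "umi": [self.umi.offset, self.umi.length],
            "bcB": [self.bcB.offset, self.bcB.length],
            "linker": [self.linker.offset, self.linker.length],
            "bcA": [self.bcA.offset, self.bcA.length],
            "linker_seq": self.linker_seq,
            "r1_tag": [self.r1_tag.offset, self.r1_tag.length],
            "read2_length": self.read2_length,
        }
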