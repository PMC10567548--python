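"""Paired FASTQ streaming (gzipped or plain) on top of Biopython's
FastqGeneralIterator."""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterator

from Bio.SeqIO.QualityIO import FastqGeneralIterator

from spatialcite.errors import InputError


def _open_text(path: str | Path):
    path = Path(path)
    if not path.exists():
        raise InputError(f"FASTQ file not found: {path}")
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def read_fastq(path: str | Path) -> Iterator[tuple[str, str, str]]:
    """Yield (id, seq, qual); id is the header token before whitespace."""
    with _open_text(path) as fh:
        try:
            for title, seq, qual in FastqGeneralIterator(fh):
                yield title.split()[0], seq, qual
        except ValueError as exc:
            raise InputError(f"truncated or malformed FASTQ {path}: {exc}") from exc


def read_fastq_pairs(
    r1_path: str | Path, r2_path: str | Path
) -> Iterator[tuple[str, str, str]]:
    """Yield (read_id, r1_seq, r2_seq) for a read pair, enforcing id agreement."""
    it1, it2 = read_fastq(r1_path), read_fastq(r2_path)
    n = 0
    for (id1, seq1, _), (id2, seq2, _) in zip(it1, it2):
        n += 1
        if id1 != id2:
            raise InputError(
                f"R1/R2 record ids differ at record {n}: {id1!r} vs {id2!r}"
            )
        yield id1, seq1, seq2
    if next(it1, None) is not None or next(it2, None) is not None:
        raise InputError(
            f"R1/R2 have different record counts (paired through record {n})"
        )


class FastqWriter:
    """Gzipped 4-line FASTQ writer with constant 'I' (Phred 40) qualities."""

    def __init__(self, path: str | Path):
        self.path = Path(path)
        self._fh = gzip.open(self.path, "wt")

    def write(self, read_id: str, seq: str) -> None:
        self._fh.write(f"@{read_id}\n{seq}\n+\n{'I' * len(seq)}\n")

    def close(self) -> None:
        self._fh.close()

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        self.close()
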