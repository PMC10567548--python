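"""Spatial barcode whitelists and Hamming-distance utilities.

The assay addresses each tissue pixel by a pair of 8-nt spatial barcodes:
barcode A indexes the row (first microfluidic flow), barcode B the column
(perpendicular second flow). A whitelist is the ordered table of the N
barcodes used on one axis (N=50 channels by default, i.e. A1..A50 /
B1..B50). Error correction against a whitelist is only safe when
2*max_hamming < min pairwise distance; loading reports that margin.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from spatialcite.errors import ConfigError

DNA_ALPHABET = "ACGT"
_DNA_SET = frozenset(DNA_ALPHABET)


def hamming(a: str, b: str) -> int:
    """Hamming distance between two equal-length strings."""
    if len(a) != len(b):
        raise ValueError(f"hamming: length mismatch ({len(a)} vs {len(b)})")
    return sum(x != y for x, y in zip(a, b))


def is_dna(seq: str) -> bool:
    return bool(seq) and set(seq) <= _DNA_SET


@dataclass
class BarcodeWhitelist:
    """Ordered barcode table for one spatial axis.

    Parameters
    ----------
    axis : {"A", "B"}
        "A" barcodes index grid rows, "B" barcodes index grid columns.
    entries : list of (index, seq)
        1-based contiguous indices and equal-length DNA barcodes.
    """

    axis: str
    entries: list[tuple[int, str]]
    min_pairwise_distance: int = field(init=False, default=0)

    def __post_init__(self) -> None:
        if self.axis not in ("A", "B"):
            raise ConfigError(f"whitelist axis must be 'A' or 'B', got {self.axis!r}")
        if not self.entries:
            raise ConfigError("whitelist has no entries")
        seqs = [s for _, s in self.entries]
        lengths = {len(s) for s in seqs}
        if len(lengths) != 1:
            raise ConfigError(f"whitelist barcode lengths differ: {sorted(lengths)}")
        for i, s in self.entries:
            if not is_dna(s):
                raise ConfigError(f"whitelist entry {i}: non-ACGT barcode {s!r}")
        if len(set(seqs)) != len(seqs):
            dup = [s for s in set(seqs) if seqs.count(s) > 1]
            raise ConfigError(f"duplicate barcode sequence(s) in whitelist: {dup}")
        indices = [i for i, _ in self.entries]
        if indices != list(range(1, len(indices) + 1)):
            raise ConfigError(
                f"whitelist indices must be contiguous 1..N, got {indices[:5]}..."
            )
        self.min_pairwise_distance = min(
            (hamming(a, b) for a, b in itertools.combinations(seqs, 2)),
            default=len(seqs[0]),
        )

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def barcode_length(self) -> int:
        return len(self.entries[0][1])

    @property
    def sequences(self) -> list[str]:
        return [s for _, s in self.entries]

    def seq(self, index: int) -> str:
        """Barcode sequence for a 1-based index."""
        return self.entries[index - 1][1]

    def correction_is_safe(self, max_hamming: int) -> bool:
        """True when correction radius cannot cross the midpoint between codes."""
        return 2 * max_hamming < self.min_pairwise_distance

    def build_matcher(self, max_hamming: int) -> dict[str, tuple[int, int]]:
        """Precompute seq -> (index, distance) for all sequences within
        `max_hamming` of a whitelist barcode. Ambiguous sequences (tied
        minimal distance to >=2 barcodes) map to (0, distance); exact
        matches always win. Used by demux for O(1) per-read lookup.
        """
        table: dict[str, tuple[int, int]] = {}
        for idx, seq in self.entries:
            for mutant, dist in _neighbourhood(seq, max_hamming):
                prev = table.get(mutant)
                if prev is None or dist < prev[1]:
                    table[mutant] = (idx, dist)
                elif dist == prev[1] and prev[0] != idx:
                    table[mutant] = (0, dist)  # tie -> ambiguous sentinel
        return table


def _neighbourhood(seq: str, max_hamming: int):
    """Yield (mutant, distance) for all sequences within Hamming max_hamming."""
    n = len(seq)
    yield seq, 0
    for d in range(1, max_hamming + 1):
        for positions in itertools.combinations(range(n), d):
            choices = [[b for b in DNA_ALPHABET if b != seq[p]] for p in positions]
            for subs in itertools.product(*choices):
                mutant = list(seq)
                for p, b in zip(positions, subs):
                    mutant[p] = b
                yield "".join(mutant), d


def load_whitelist(
    path: str | Path, axis: str, max_hamming: int = 1
) -> BarcodeWhitelist:
    """Load a whitelist from a 2-column TSV (index, seq).

    No header; lines starting with '#' are comments. Warns when the
    correction radius `max_hamming` is unsafe for the whitelist's minimum
    pairwise distance (2*max_hamming must be < min distance), in which
    case callers should fall back to exact matching.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"whitelist file not found: {path}")
    entries: list[tuple[int, str]] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            parts = line.split()
        if len(parts) < 2:
            raise ConfigError(f"{path}:{lineno}: expected 'index<TAB>seq'")
        try:
            idx = int(parts[0])
        except ValueError as exc:
            raise ConfigError(f"{path}:{lineno}: non-integer index {parts[0]!r}") from exc
        entries.append((idx, parts[1].upper()))
    if not entries:
        raise ConfigError(f"whitelist file is empty: {path}")
    wl = BarcodeWhitelist(axis=axis, entries=entries)
    if not wl.correction_is_safe(max_hamming):
        warnings.warn(
            f"whitelist {path} min pairwise distance {wl.min_pairwise_distance} "
            f"does not support Hamming-{max_hamming} correction "
            f"(need 2*{max_hamming} < {wl.min_pairwise_distance}); "
            "falling back to exact matching is recommended",
            stacklevel=2,
        )
    return wl


def write_whitelist(wl: BarcodeWhitelist, path: str | Path) -> None:
    """Write a whitelist as index<TAB>seq lines (round-trips load_whitelist)."""
    with open(path, "w") as fh:
        for idx, seq in wl.entries:
            fh.write(f"{idx}\t{seq}\n")


def generate_fixture_whitelists(
    n: int = 50,
    length: int = 8,
    min_dist: int = 3,
    seed: int = 0,
    max_attempts: int = 200_000,
) -> tuple[BarcodeWhitelist, BarcodeWhitelist]:
    """Generate disjoint A and B whitelists by greedy rejection sampling.

    Draws random codes and keeps those at Hamming >= min_dist from every
    code accepted so far (across both axes, so A and B are disjoint).
    Deterministic given seed.

    Raises
    ------
    ConfigError
        If 2n codes cannot be found within `max_attempts` draws — the
        (n, length, min_dist) combination is infeasible or too tight.
    """
    if min_dist > length:
        raise ConfigError(
            f"min_dist {min_dist} exceeds barcode length {length}: infeasible"
        )
    rng = np.random.default_rng(seed)
    accepted: list[str] = []
    attempts = 0
    while len(accepted) < 2 * n:
        attempts += 1
        if attempts > max_attempts:
            raise ConfigError(
                f"could not find {2 * n} codes of length {length} with pairwise "
                f"Hamming >= {min_dist} after {max_attempts} attempts"
            )
        cand = "".join(DNA_ALPHABET[i] for i in rng.integers(0, 4, size=length))
        if all(hamming(cand, prev) >= min_dist for prev in accepted):
            accepted.append(cand)
    wl_a = BarcodeWhitelist("A", list(enumerate(accepted[:n], start=1)))
    wl_b = BarcodeWhitelist("B", list(enumerate(accepted[n:], start=1)))
    return wl_a, wl_b
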