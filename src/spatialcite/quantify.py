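"""Feature assignment and UMI counting into spatial matrices.

ADT reads are matched to antibodies by the tag region of Read 1 (unique
nearest panel tag within a Hamming radius, ties dropped). RNA reads are
assigned by a toy exact k-mer index over a small transcriptome — a
stand-in, with the same interface, for a genome aligner; externally
produced read->gene tables can be supplied instead. Molecules are then
counted as distinct UMIs per (pixel, feature), exactly or with the
directional one-mismatch network rule.
"""

from __future__ import annotations

from collections import defaultdict
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd
import scipy.sparse as sp

from Bio import SeqIO

from spatialcite.barcodes import hamming
from spatialcite.demux import DemuxRecord
from spatialcite.errors import ConfigError, DataError
from spatialcite.layout import Segment
from spatialcite.matrix import PixelAddress, SpatialCountMatrix
from spatialcite.panel import ADTPanel

_AMBIGUOUS = object()


def match_adt_tag(
    payload: str,
    panel: ADTPanel,
    max_hamming: int = 1,
    r1_tag: Segment | tuple[int, int] = (0, 15),
) -> str | None:
    """Antibody id for the tag region of an ADT Read 1, or None.

    The unique panel tag at minimal Hamming distance <= max_hamming wins;
    exact matches win immediately; a tie at the minimal distance is a
    no-match (None).
    """
    if not isinstance(r1_tag, Segment):
        r1_tag = Segment(*r1_tag)
    if len(payload) < r1_tag.end:
        return None
    tag = r1_tag.slice(payload)
    best: str | None = None
    best_d = max_hamming + 1
    tied = False
    for entry in panel:
        d = hamming(tag, entry.tag_seq)
        if d == 0:
            return entry.antibody_id
        if d < best_d:
            best, best_d, tied = entry.antibody_id, d, False
        elif d == best_d and best_d <= max_hamming:
            tied = True
    if best_d > max_hamming or tied:
        return None
    return best


class TranscriptomeIndex:
    """Exact k-mer -> gene lookup over a toy transcriptome.

    Every k-mer of every transcript maps to its gene; k-mers shared by two
    or more genes are marked ambiguous and never support an assignment.
    """

    def __init__(self, gene_seqs: dict[str, str], k: int = 31):
        if k < 1:
            raise ConfigError(f"k must be positive, got {k}")
        if not gene_seqs:
            raise ConfigError("empty transcriptome")
        self.k = k
        self.genes = sorted(gene_seqs)
        self.gene_seqs = dict(gene_seqs)
        self._kmers: dict[str, object] = {}
        for gene, seq in gene_seqs.items():
            seq = seq.upper()
            for i in range(len(seq) - k + 1):
                kmer = seq[i : i + k]
                prev = self._kmers.get(kmer)
                if prev is None:
                    self._kmers[kmer] = gene
                elif prev is not _AMBIGUOUS and prev != gene:
                    self._kmers[kmer] = _AMBIGUOUS

    @classmethod
    def from_fasta(cls, path: str | Path, k: int = 31) -> "TranscriptomeIndex":
        path = Path(path)
        if not path.exists():
            raise ConfigError(f"transcriptome FASTA not found: {path}")
        seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
        if not seqs:
            raise ConfigError(f"no sequences in transcriptome FASTA: {path}")
        return cls(seqs, k=k)

    def assign(self, payload: str) -> str | None:
        """Unique gene hit by the payload's k-mers, else None (0 or >=2 genes)."""
        k = self.k
        if len(payload) < k:
            return None
        hits: set[str] = set()
        payload = payload.upper()
        for i in range(len(payload) - k + 1):
            g = self._kmers.get(payload[i : i + k])
            if g is _AMBIGUOUS:
                return None
            if g is not None:
                hits.add(g)  # type: ignore[arg-type]
                if len(hits) > 1:
                    return None
        if len(hits) == 1:
            return hits.pop()
        return None


def assign_transcript_toy(payload: str, index: TranscriptomeIndex) -> str | None:
    """Functional wrapper around TranscriptomeIndex.assign."""
    return index.assign(payload)


def assign_features(
    records: Iterable[DemuxRecord],
    modality: str,
    panel: ADTPanel | None = None,
    transcriptome: TranscriptomeIndex | None = None,
    max_hamming_tag: int = 1,
    r1_tag: Segment | tuple[int, int] | None = None,
    external_assignments: dict[str, str] | None = None,
) -> Iterator[tuple[PixelAddress, str, str]]:
    """Yield (pixel, feature_id, umi_seq) for records whose payload is
    assignable. `external_assignments` (read_id -> feature) plugs in an
    upstream aligner's output and bypasses the toy assigners."""
    matcher: dict[str, tuple[str | None, int]] | None = None
    if external_assignments is None and modality == "protein":
        if panel is None:
            raise ConfigError("protein assignment requires a panel")
        matcher = panel.build_matcher(max_hamming_tag)
    for rec in records:
        if external_assignments is not None:
            feature = external_assignments.get(rec.read_id)
        elif modality == "protein":
            tag_seg = r1_tag if r1_tag is not None else Segment(0, panel.tag_length)
            if len(rec.payload_seq) < tag_seg.end:
                feature = None
            else:
                hit = matcher.get(tag_seg.slice(rec.payload_seq))
                feature = hit[0] if hit is not None else None
        elif modality == "RNA":
            if transcriptome is None:
                raise ConfigError("RNA assignment requires a transcriptome index")
            feature = transcriptome.assign(rec.payload_seq)
        else:
            raise ConfigError(f"unknown modality {modality!r}")
        if feature is not None:
            yield rec.pixel, feature, rec.umi_seq


def _directional_count(umi_counts: dict[str, int]) -> int:
    """Number of molecule networks under the directional adjacency rule:
    an edge u -> v exists when Hamming(u, v) == 1 and count[u] >= 2*count[v] - 1;
    networks are grown from the most abundant unvisited UMI."""
    umis = sorted(umi_counts, key=lambda u: (-umi_counts[u], u))
    # adjacency restricted to Hamming-1 pairs
    neighbours: dict[str, list[str]] = defaultdict(list)
    if len(umis) > 1:
        for i, u in enumerate(umis):
            for v in umis[i + 1 :]:
                if hamming(u, v) == 1:
                    neighbours[u].append(v)
                    neighbours[v].append(u)
    visited: set[str] = set()
    networks = 0
    for root in umis:
        if root in visited:
            continue
        networks += 1
        stack = [root]
        visited.add(root)
        while stack:
            u = stack.pop()
            for v in neighbours[u]:
                if v not in visited and umi_counts[u] >= 2 * umi_counts[v] - 1:
                    visited.add(v)
                    stack.append(v)
    return networks


def collapse_umis(
    records: Iterable[tuple[PixelAddress, str, str]],
    mode: str = "exact",
) -> dict[tuple[PixelAddress, str], int]:
    """Molecule counts per (pixel, feature) from (pixel, feature, umi) records.

    exact
        Count distinct UMI sequences (the default of the feature-barcode
        counting tools this mirrors).
    directional1mm
        Merge UMIs into networks via the directional one-mismatch rule
        (edge parent->child when Hamming distance is 1 and
        count(parent) >= 2*count(child) - 1) and count the networks.
    """
    if mode not in ("exact", "directional1mm"):
        raise ConfigError(f"unknown UMI collapse mode {mode!r}")
    groups: dict[tuple[PixelAddress, str], dict[str, int]] = defaultdict(
        lambda: defaultdict(int)
    )
    for pixel, feature, umi in records:
        groups[(pixel, feature)][umi] += 1
    if mode == "exact":
        return {key: len(umis) for key, umis in groups.items()}
    return {key: _directional_count(umis) for key, umis in groups.items()}


def build_matrix(
    counts: dict[tuple[PixelAddress, str], int],
    modality: str,
    panel_or_geneset: ADTPanel | Iterable[str],
    grid: tuple[int, int],
    drop_unobserved_genes: bool = True,
    pixel_filter: set[PixelAddress] | None = None,
) -> SpatialCountMatrix:
    """Assemble the sparse features x pixels matrix.

    Feature order is panel order for protein (all-zero rows retained so
    the panel size stays structurally visible) and lexicographic for RNA
    (never-observed genes dropped unless `drop_unobserved_genes=False`).
    Pixels are those with >=1 counted molecule, in (row, col) order,
    optionally intersected with an explicit `pixel_filter` (the stand-in
    for image-based cropping to the tissue-covered region).
    """
    n_rows, n_cols = grid
    if isinstance(panel_or_geneset, ADTPanel):
        features = panel_or_geneset.antibody_ids
    else:
        # keep the caller's order (panel order / pre-sorted gene list)
        features = list(dict.fromkeys(panel_or_geneset))
    known = set(features)
    observed_features = {f for (_, f) in counts}
    unknown = observed_features - known
    if unknown:
        raise DataError(f"counts contain unknown feature(s): {sorted(unknown)[:5]}")
    if modality == "RNA" and drop_unobserved_genes:
        features = [f for f in features if f in observed_features]
    pixels = sorted({p for (p, _) in counts})
    for p in pixels:
        if p.row > n_rows or p.col > n_cols:
            raise DataError(f"pixel {p.label} outside {n_rows}x{n_cols} grid")
    if pixel_filter is not None:
        pixels = [p for p in pixels if p in pixel_filter]
    fi = {f: i for i, f in enumerate(features)}
    pi = {p: j for j, p in enumerate(pixels)}
    rows, cols, data = [], [], []
    for (p, f), n in sorted(counts.items()):
        if n and p in pi:
            rows.append(fi[f])
            cols.append(pi[p])
            data.append(n)
    mat = sp.coo_matrix(
        (data, (rows, cols)), shape=(len(features), len(pixels)), dtype=np.int64
    )
    return SpatialCountMatrix(modality, features, pixels, mat)


def load_external_assignments(path: str | Path) -> dict[str, str]:
    """Read a read_id -> feature TSV produced by an external aligner."""
    df = pd.read_csv(path, sep="\t", header=None, names=["read_id", "feature"], dtype=str)
    return dict(zip(df["read_id"], df["feature"]))
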