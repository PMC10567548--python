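"""Run configuration and the end-to-end pipeline driver.

RunConfig validates a YAML mapping (unknown keys rejected), materializes
every default, and hashes its canonical form so the output manifest can
prove which settings produced which matrices. `run_pipeline` wires
demux -> feature assignment -> UMI collapse -> matrices -> QC ->
normalization -> scoring -> pseudo-bulk, writing each product atomically
under the output directory.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from spatialcite import __version__
from spatialcite.barcodes import load_whitelist
from spatialcite.demux import demux_library
from spatialcite.errors import ConfigError, InputError
from spatialcite.layout import ReadLayout
from spatialcite.matrix import PixelAddress
from spatialcite.panel import load_panel
from spatialcite.qc import clr_normalize, lognorm_rna, pseudobulk, qc_metrics, signature_score
from spatialcite.quantify import (
    TranscriptomeIndex,
    assign_features,
    build_matrix,
    collapse_umis,
)

# PD-1's gene symbol is PDCD1; ADT ids follow the antibody naming.
DEFAULT_SIGNATURE_GENES = ["LAG3", "PDCD1", "CXCR6"]
DEFAULT_PROTEIN_SIGNATURE_MAP = {
    "LAG3": "anti-LAG3",
    "PDCD1": "anti-PD-1",
    "CXCR6": "anti-CXCR6",
}

_CONFIG_KEYS = {
    "layout",
    "whitelist_a",
    "whitelist_b",
    "panel",
    "transcriptome",
    "max_hamming_bc",
    "max_hamming_linker",
    "max_hamming_tag",
    "collapse_mode",
    "clr_margin",
    "lognorm_scale",
    "kmer_size",
    "drop_unobserved_genes",
    "min_total_umi_pseudobulk",
    "signature_genes",
    "protein_signature_map",
    "pixel_filter",
    "seed",
}


@dataclass
class RunConfig:
    whitelist_a: str
    whitelist_b: str
    panel: str
    transcriptome: str
    layout: ReadLayout = field(default_factory=ReadLayout)
    max_hamming_bc: int = 1
    max_hamming_linker: int = 2
    max_hamming_tag: int = 1
    collapse_mode: str = "exact"
    clr_margin: str = "per_pixel"
    lognorm_scale: float = 10_000.0
    kmer_size: int = 31
    drop_unobserved_genes: bool = True
    min_total_umi_pseudobulk: int = 10
    signature_genes: list[str] = field(
        default_factory=lambda: list(DEFAULT_SIGNATURE_GENES)
    )
    protein_signature_map: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_PROTEIN_SIGNATURE_MAP)
    )
    pixel_filter: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.collapse_mode not in ("exact", "directional1mm"):
            raise ConfigError(f"collapse_mode invalid: {self.collapse_mode!r}")
        if self.clr_margin not in ("per_pixel", "per_feature"):
            raise ConfigError(f"clr_margin invalid: {self.clr_margin!r}")
        for name in ("max_hamming_bc", "max_hamming_linker", "max_hamming_tag"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        for name in ("whitelist_a", "whitelist_b", "panel", "transcriptome"):
            p = getattr(self, name)
            if p and not Path(p).exists():
                raise ConfigError(f"{name} file not found: {p}")
        if self.pixel_filter and not Path(self.pixel_filter).exists():
            raise ConfigError(f"pixel_filter file not found: {self.pixel_filter}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        if not path.exists():
            raise ConfigError(f"config file not found: {path}")
        doc = yaml.safe_load(path.read_text()) or {}
        if not isinstance(doc, dict):
            raise ConfigError(f"config {path} is not a mapping")
        unknown = set(doc) - _CONFIG_KEYS
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        if "layout" in doc:
            doc["layout"] = ReadLayout.from_dict(doc["layout"])
        # resolve relative paths against the config file's directory
        for key in ("whitelist_a", "whitelist_b", "panel", "transcriptome", "pixel_filter"):
            if doc.get(key):
                doc[key] = str((path.parent / doc[key]).resolve())
        missing = {"whitelist_a", "whitelist_b", "panel", "transcriptome"} - set(doc)
        if missing:
            raise ConfigError(f"config missing required key(s): {sorted(missing)}")
        return cls(**doc)

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in sorted(_CONFIG_KEYS)}
        d["layout"] = self.layout.to_dict()
        return d

    def config_hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]

    def load_pixel_filter(self) -> set[PixelAddress] | None:
        """Optional pixel-list file (row<TAB>col per line) standing in for
        image-based cropping to the tissue-covered region."""
        if not self.pixel_filter:
            return None
        out = set()
        for line in Path(self.pixel_filter).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            r, c = line.split()[:2]
            out.add(PixelAddress(int(r), int(c)))
        return out


def run_pipeline(
    config: RunConfig,
    rna_fastq: tuple[str | Path, str | Path] | None,
    adt_fastq: tuple[str | Path, str | Path] | None,
    outdir: str | Path,
) -> dict:
    """Run demux -> count -> QC -> normalize -> score for both libraries.

    Either library may be None (single-modality runs). Returns the
    manifest dict (also written to `outdir`/manifest.json).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    wl_a = load_whitelist(config.whitelist_a, "A", config.max_hamming_bc)
    wl_b = load_whitelist(config.whitelist_b, "B", config.max_hamming_bc)
    panel = load_panel(config.panel)
    grid = (len(wl_a), len(wl_b))
    pixel_filter = config.load_pixel_filter()
    manifest: dict = {
        "spatialcite_version": __version__,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "stages": {},
    }

    def stage(modality: str, fastq_pair, assigner_kwargs, features):
        for p in fastq_pair:
            if not Path(p).exists():
                raise InputError(f"{modality} FASTQ not found: {p}")
        records, stats = demux_library(
            (str(fastq_pair[0]), str(fastq_pair[1])),
            config.layout,
            wl_a,
            wl_b,
            max_hamming_bc=config.max_hamming_bc,
            max_hamming_linker=config.max_hamming_linker,
            modality=modality,
        )
        triples = assign_features(records, modality, **assigner_kwargs)
        counts = collapse_umis(triples, mode=config.collapse_mode)
        matrix = build_matrix(
            counts,
            modality,
            features,
            grid,
            drop_unobserved_genes=config.drop_unobserved_genes,
            pixel_filter=pixel_filter,
        )
        manifest["stages"][modality] = {"demux": stats.as_dict()}
        if not stats.conserved():  # defensive; demux guarantees this
            raise InputError(f"{modality} demux stats lost reads")
        return matrix

    products: dict[str, object] = {}
    if rna_fastq is not None:
        tx_index = TranscriptomeIndex.from_fasta(config.transcriptome, k=config.kmer_size)
        rna = stage("RNA", rna_fastq, {"transcriptome": tx_index}, tx_index.genes)
        rna.write_mtx(outdir / "rna")
        rna.write_long_tsv(outdir / "rna" / "counts_long.tsv")
        _write_qc(rna, outdir / "rna")
        lognorm = lognorm_rna(rna, scale=config.lognorm_scale)
        lognorm.write_mtx(outdir / "rna_lognorm")
        present = [g for g in config.signature_genes if g in lognorm.features]
        if present:
            score = signature_score(lognorm, config.signature_genes)
            score.to_frame().to_csv(outdir / "tph_score.tsv", sep="\t", index=False)
            manifest["stages"]["RNA"]["signature_genes_used"] = score.genes_used
        products["rna"] = rna
    if adt_fastq is not None:
        prot = stage(
            "protein",
            adt_fastq,
            {"panel": panel, "max_hamming_tag": config.max_hamming_tag},
            panel,
        )
        prot.write_mtx(outdir / "protein")
        prot.write_long_tsv(outdir / "protein" / "counts_long.tsv")
        _write_qc(prot, outdir / "protein")
        clr = clr_normalize(prot, margin=config.clr_margin)
        clr.write_mtx(outdir / "protein_clr")
        pseudobulk(prot, min_total_umi=config.min_total_umi_pseudobulk).to_csv(
            outdir / "protein_pseudobulk.tsv", sep="\t"
        )
        products["protein"] = prot
    if not products:
        raise ConfigError("no input libraries given (both rna and adt are None)")

    tmp = outdir / ".manifest.json.tmp"
    tmp.write_text(json.dumps(manifest, indent=2, default=str))
    tmp.replace(outdir / "manifest.json")
    manifest["_products"] = products
    return manifest


def _write_qc(matrix, stage_dir: Path) -> None:
    import pandas as pd

    per_pixel, summary = qc_metrics(matrix)
    stage_dir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {
            "pixel": [q.pixel.label for q in per_pixel],
            "row": [q.pixel.row for q in per_pixel],
            "col": [q.pixel.col for q in per_pixel],
            "umi_count": [q.umi_count for q in per_pixel],
            "feature_count": [q.feature_count for q in per_pixel],
        }
    ).to_csv(stage_dir / "qc.tsv", sep="\t", index=False)
    (stage_dir / "qc_summary.json").write_text(json.dumps(summary.as_dict(), indent=2))
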