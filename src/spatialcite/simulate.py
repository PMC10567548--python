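"""Ground-truth tissue simulator emitting paired FASTQ libraries.

A TissueModel partitions a pixel grid into spatial domains (emulating
anatomical compartments like red/white pulp or germinal-center zones),
each with its own per-pixel mean molecule counts for genes and antibodies.
Molecule counts are Poisson around those means; every molecule gets a
uniform-random UMI and is emitted as >=1 read pair (geometric PCR
duplication), with Read 2 assembled from the pixel's spatial barcodes per
the layout and Read 1 carrying the ADT tag or a random transcript
substring. Uniform substitution errors are applied last. The GroundTruth
object records every molecule and is the oracle for all recovery tests;
because UMIs are drawn uniformly, collisions can merge molecules, so the
recoverable truth is the distinct-(UMI, feature, pixel) matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from spatialcite.barcodes import BarcodeWhitelist, DNA_ALPHABET
from spatialcite.errors import ConfigError, DataError
from spatialcite.fastq import FastqWriter
from spatialcite.layout import ReadLayout
from spatialcite.matrix import PixelAddress, SpatialCountMatrix
from spatialcite.panel import ADTPanel

_BASES = np.frombuffer(DNA_ALPHABET.encode(), dtype=np.uint8)


def default_gene_names(n: int) -> list[str]:
    """Toy gene set; the first three are the Tph signature trio (LAG3,
    PDCD1 i.e. PD-1, CXCR6) so signature-scoring demos work out of the box."""
    named = ["LAG3", "PDCD1", "CXCR6"]
    extra = [f"GENE{i:03d}" for i in range(4, n + 1)]
    return (named + extra)[:n]


def default_antibody_names(n: int, n_isotype: int = 0) -> list[str]:
    named = ["anti-LAG3", "anti-PD-1", "anti-CXCR6"]
    extra = [f"ADT{i:03d}" for i in range(4, n - n_isotype + 1)]
    iso = [f"IsoCtrl{i:02d}" for i in range(1, n_isotype + 1)]
    return (named + extra)[: n - n_isotype] + iso


@dataclass
class Domain:
    """One spatial compartment: a pixel mask plus mean molecules/pixel."""

    domain_id: str
    mask: np.ndarray  # bool (n_rows, n_cols)
    rna_profile: dict[str, float]
    protein_profile: dict[str, float]


@dataclass
class TissueModel:
    grid: tuple[int, int]
    domains: list[Domain]
    background_rate: float = 0.0

    def __post_init__(self) -> None:
        n_rows, n_cols = self.grid
        if n_rows < 1 or n_cols < 1 or n_rows > 50 or n_cols > 50:
            raise ConfigError(f"grid must be within (1,1)..(50,50), got {self.grid}")
        if self.background_rate < 0:
            raise ConfigError("background_rate must be >= 0")
        cover = np.zeros(self.grid, dtype=int)
        for d in self.domains:
            if d.mask.shape != self.grid:
                raise ConfigError(
                    f"domain {d.domain_id} mask shape {d.mask.shape} != grid {self.grid}"
                )
            if any(v < 0 for v in d.rna_profile.values()) or any(
                v < 0 for v in d.protein_profile.values()
            ):
                raise ConfigError(f"domain {d.domain_id}: negative profile mean")
            cover += d.mask.astype(int)
        if not np.all(cover == 1):
            raise ConfigError("domain masks must partition the grid exactly")

    @property
    def genes(self) -> list[str]:
        out: set[str] = set()
        for d in self.domains:
            out.update(d.rna_profile)
        return sorted(out)

    @property
    def antibodies(self) -> list[str]:
        out: set[str] = set()
        for d in self.domains:
            out.update(d.protein_profile)
        return sorted(out)

    def domain_of(self) -> np.ndarray:
        """Integer map of domain index per pixel."""
        idx = np.full(self.grid, -1, dtype=int)
        for i, d in enumerate(self.domains):
            idx[d.mask] = i
        return idx

    def to_yaml(self, path: str | Path) -> None:
        doc = {
            "grid": list(self.grid),
            "background_rate": float(self.background_rate),
            "domains": [
                {
                    "domain_id": d.domain_id,
                    "mask": ["".join("1" if v else "0" for v in row) for row in d.mask],
                    "rna_profile": {k: float(v) for k, v in d.rna_profile.items()},
                    "protein_profile": {
                        k: float(v) for k, v in d.protein_profile.items()
                    },
                }
                for d in self.domains
            ],
        }
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "TissueModel":
        doc = yaml.safe_load(Path(path).read_text())
        domains = [
            Domain(
                domain_id=d["domain_id"],
                mask=np.array([[c == "1" for c in row] for row in d["mask"]]),
                rna_profile=dict(d["rna_profile"]),
                protein_profile=dict(d["protein_profile"]),
            )
            for d in doc["domains"]
        ]
        return cls(
            grid=tuple(doc["grid"]),
            domains=domains,
            background_rate=float(doc.get("background_rate", 0.0)),
        )


@dataclass(frozen=True)
class ErrorModel:
    substitution_rate: float = 0.0
    pcr_duplication: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.substitution_rate < 0.25:
            raise ConfigError(
                f"substitution_rate must be in [0, 0.25), got {self.substitution_rate}"
            )
        if self.pcr_duplication < 1:
            raise ConfigError("pcr_duplication must be >= 1")


class GroundTruth:
    """Per-molecule record of what the simulator emitted.

    ``molecules`` has one row per molecule: molecule_id, row, col,
    feature, modality, umi, n_reads. Matrices and the per-read provenance
    log are derived views.
    """

    def __init__(self, molecules: pd.DataFrame, grid: tuple[int, int],
                 protein_features: list[str]):
        self.molecules = molecules
        self.grid = grid
        self.protein_features = list(protein_features)

    def _subset(self, modality: str) -> pd.DataFrame:
        return self.molecules[self.molecules["modality"] == modality]

    def total_reads(self, modality: str) -> int:
        return int(self._subset(modality)["n_reads"].sum())

    def total_molecules(self, modality: str) -> int:
        return int(len(self._subset(modality)))

    def _features(self, modality: str) -> list[str]:
        if modality == "protein":
            return self.protein_features
        return sorted(self._subset("RNA")["feature"].unique())

    def molecule_matrix(self, modality: str) -> SpatialCountMatrix:
        """True molecule counts per (pixel, feature)."""
        sub = self._subset(modality)
        counts = sub.groupby(["row", "col", "feature"]).size()
        return self._to_matrix(counts, modality)

    def distinct_umi_matrix(self, modality: str) -> SpatialCountMatrix:
        """Distinct (UMI, feature, pixel) truth — what a perfect pipeline
        recovers given UMI collisions."""
        sub = self._subset(modality)
        counts = sub.groupby(["row", "col", "feature"])["umi"].nunique()
        return self._to_matrix(counts, modality)

    def _to_matrix(self, counts: pd.Series, modality: str) -> SpatialCountMatrix:
        from spatialcite.quantify import build_matrix

        d = {
            (PixelAddress(int(r), int(c)), f): int(n)
            for (r, c, f), n in counts.items()
        }
        return build_matrix(
            d, modality, self._features(modality), self.grid,
            drop_unobserved_genes=False,
        )

    def pixel_of_read(self) -> dict[str, tuple[int, int]]:
        """Provenance: read_id -> (row, col). Read ids encode the molecule
        id, so this expands molecules by their duplicate count."""
        out: dict[str, tuple[int, int]] = {}
        for m in self.molecules.itertuples(index=False):
            for k in range(int(m.n_reads)):
                out[f"{m.molecule_id}d{k}"] = (int(m.row), int(m.col))
        return out

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.molecules.to_csv(outdir / "molecules.tsv", sep="\t", index=False)
        for modality, name in (("RNA", "truth_rna"), ("protein", "truth_protein")):
            if self.total_molecules(modality):
                self.distinct_umi_matrix(modality).write_mtx(outdir, prefix=f"{name}_")


@dataclass
class SimulationResult:
    rna_r1: Path
    rna_r2: Path
    adt_r1: Path
    adt_r2: Path
    truth: GroundTruth


def _random_umis(rng: np.random.Generator, n: int, length: int) -> list[str]:
    arr = _BASES[rng.integers(0, 4, size=(n, length))]
    return [bytes(row).decode() for row in arr]


def _mutate(seq: str, rng: np.random.Generator, rate: float) -> str:
    """Apply uniform substitutions; each hit base moves to one of the
    other three bases."""
    if rate <= 0:
        return seq
    hits = np.nonzero(rng.random(len(seq)) < rate)[0]
    if hits.size == 0:
        return seq
    out = list(seq)
    for i in hits:
        choices = [b for b in DNA_ALPHABET if b != out[i]]
        out[i] = choices[rng.integers(0, 3)]
    return "".join(out)


def _assemble_read2(layout: ReadLayout, umi: str, bc_b: str, bc_a: str) -> str:
    length = layout.read2_length or layout.span
    out = ["A"] * length
    for seg, text in (
        (layout.umi, umi),
        (layout.bcB, bc_b),
        (layout.linker, layout.linker_seq),
        (layout.bcA, bc_a),
    ):
        out[seg.offset : seg.end] = list(text)
    return "".join(out)


def simulate_run(
    model: TissueModel,
    panel: ADTPanel,
    transcriptome: str | Path | dict[str, str],
    whitelists: tuple[BarcodeWhitelist, BarcodeWhitelist],
    layout: ReadLayout,
    err: ErrorModel,
    outdir: str | Path,
    umi_length: int | None = None,
    insert_length: int = 90,
) -> SimulationResult:
    """Simulate both sequencing libraries plus their ground truth.

    Writes four gzipped FASTQs under `outdir` (rna_R1/R2, adt_R1/R2).
    Byte-identical output for identical inputs and ``err.seed``.
    """
    wl_a, wl_b = whitelists
    n_rows, n_cols = model.grid
    if n_rows > len(wl_a) or n_cols > len(wl_b):
        raise ConfigError(
            f"grid {model.grid} exceeds whitelist sizes ({len(wl_a)}, {len(wl_b)})"
        )
    if isinstance(transcriptome, (str, Path)):
        from Bio import SeqIO

        tx = {r.id: str(r.seq).upper() for r in SeqIO.parse(str(transcriptome), "fasta")}
    else:
        tx = {k: v.upper() for k, v in transcriptome.items()}
    missing_genes = set(model.genes) - set(tx)
    if missing_genes:
        raise DataError(f"genes not in transcriptome: {sorted(missing_genes)[:5]}")
    known_abs = set(panel.antibody_ids)
    missing_abs = set(model.antibodies) - known_abs
    if missing_abs:
        raise DataError(f"antibodies not in panel: {sorted(missing_abs)[:5]}")

    umi_length = umi_length or layout.umi.length
    rng = np.random.default_rng(err.seed)
    tag_of = {e.antibody_id: e.tag_seq for e in panel}
    adt_r1_len = max(layout.r1_tag.end + 10, 25)

    # --- draw molecules, domain by domain, in a fixed order -----------
    rows_out: list[tuple] = []  # (molecule_id, row, col, feature, modality, umi, n_reads)
    mol_counter = 0

    def draw_block(pixels: np.ndarray, feature: str, mean: float, modality: str):
        nonlocal mol_counter
        if mean <= 0 or pixels.size == 0:
            return
        counts = rng.poisson(mean, size=pixels.shape[0])
        total = int(counts.sum())
        if total == 0:
            return
        umis = _random_umis(rng, total, umi_length)
        if err.pcr_duplication > 1:
            dups = rng.geometric(1.0 / err.pcr_duplication, size=total)
        else:
            dups = np.ones(total, dtype=int)
        k = 0
        prefix = "R" if modality == "RNA" else "P"
        for (r, c), n in zip(pixels, counts):
            for _ in range(n):
                rows_out.append(
                    (
                        f"{prefix}m{mol_counter:08d}",
                        int(r),
                        int(c),
                        feature,
                        modality,
                        umis[k],
                        int(dups[k]),
                    )
                )
                mol_counter += 1
                k += 1

    for d in model.domains:
        rr, cc = np.nonzero(d.mask)
        pixels = np.column_stack([rr + 1, cc + 1])  # 1-based addresses
        for gene in sorted(d.rna_profile):
            draw_block(pixels, gene, d.rna_profile[gene], "RNA")
        for ab in panel.antibody_ids:
            mean = d.protein_profile.get(ab, 0.0) + model.background_rate
            draw_block(pixels, ab, mean, "protein")

    molecules = pd.DataFrame(
        rows_out,
        columns=["molecule_id", "row", "col", "feature", "modality", "umi", "n_reads"],
    )
    truth = GroundTruth(molecules, model.grid, panel.antibody_ids)

    # --- emit reads ---------------------------------------------------
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "rna_r1": outdir / "rna_R1.fastq.gz",
        "rna_r2": outdir / "rna_R2.fastq.gz",
        "adt_r1": outdir / "adt_R1.fastq.gz",
        "adt_r2": outdir / "adt_R2.fastq.gz",
    }
    writers = {k: FastqWriter(p) for k, p in paths.items()}
    try:
        for m in molecules.itertuples(index=False):
            bc_a = wl_a.seq(m.row)
            bc_b = wl_b.seq(m.col)
            read2 = _assemble_read2(layout, m.umi, bc_b, bc_a)
            if m.modality == "RNA":
                seq = tx[m.feature]
                if len(seq) <= insert_length:
                    insert = seq
                else:
                    start = int(rng.integers(0, len(seq) - insert_length + 1))
                    insert = seq[start : start + insert_length]
                r1_key, r2_key = "rna_r1", "rna_r2"
            else:
                # tag at the layout's Read-1 offset, poly(A) fill to length
                tag = tag_of[m.feature]
                insert = ("T" * layout.r1_tag.offset + tag + "A" * adt_r1_len)[:adt_r1_len]
                r1_key, r2_key = "adt_r1", "adt_r2"
            for k in range(int(m.n_reads)):
                rid = f"{m.molecule_id}d{k}"
                writers[r1_key].write(rid, _mutate(insert, rng, err.substitution_rate))
                writers[r2_key].write(rid, _mutate(read2, rng, err.substitution_rate))
    finally:
        for w in writers.values():
            w.close()
    return SimulationResult(
        rna_r1=paths["rna_r1"],
        rna_r2=paths["rna_r2"],
        adt_r1=paths["adt_r1"],
        adt_r2=paths["adt_r2"],
        truth=truth,
    )


# ---------------------------------------------------------------------
# Demo tissues


def _disc(n_rows: int, n_cols: int, cy: float, cx: float, r: float) -> np.ndarray:
    yy, xx = np.mgrid[0:n_rows, 0:n_cols]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2


def make_demo_tissue(
    preset: str,
    seed: int = 0,
    grid: tuple[int, int] = (10, 10),
    n_genes: int = 20,
    n_antibodies: int = 30,
    enrichment: float = 10.0,
    n_isotype: int | None = None,
) -> TissueModel:
    """Parametric demo tissues with 3–7 domains and >=10x-enriched markers.

    Presets sketch the compartment geometries seen in lymphoid and skin
    sections: ``spleen_like`` (red/white pulp + capsule ring),
    ``tonsil_like`` (follicles with light/dark zones in an extrafollicular
    background), ``skin_like`` (epidermis/dermis bands plus a focal
    infiltrate domain where the Tph trio — LAG3, PDCD1, CXCR6 — and their
    ADTs are enriched).
    """
    presets = ("spleen_like", "tonsil_like", "skin_like")
    if preset not in presets:
        raise ConfigError(f"unknown preset {preset!r}; choose from {presets}")
    rng = np.random.default_rng(seed)
    n_rows, n_cols = grid
    genes = default_gene_names(n_genes)
    if n_isotype is None:
        n_isotype = min(2, max(0, n_antibodies - 6))
    abs_ = default_antibody_names(n_antibodies, n_isotype=n_isotype)

    # isotype controls have no target: they see only background_rate
    base_rna = {g: 1.0 for g in genes}
    base_prot = {a: 0.0 if a.startswith("IsoCtrl") else 0.5 for a in abs_}

    def profile(markers_rna: list[str], markers_prot: list[str]):
        rna = dict(base_rna)
        prot = dict(base_prot)
        for g in markers_rna:
            rna[g] = base_rna[g] * enrichment
        for a in markers_prot:
            prot[a] = base_prot[a] * enrichment
        return rna, prot

    masks: list[tuple[str, np.ndarray, list[str], list[str]]] = []
    if preset == "spleen_like":
        cy, cx = rng.uniform(2, n_rows - 3), rng.uniform(2, n_cols - 3)
        white = _disc(n_rows, n_cols, cy, cx, min(n_rows, n_cols) / 4)
        capsule = np.zeros(grid, dtype=bool)
        capsule[0, :] = capsule[-1, :] = True
        capsule[:, 0] = capsule[:, -1] = True
        white &= ~capsule
        red = ~(white | capsule)
        masks = [
            ("white_pulp", white, [genes[3]], [abs_[3]]),
            ("capsule", capsule, [genes[4]], [abs_[4]]),
            ("red_pulp", red, [genes[5]], [abs_[5]]),
        ]
    elif preset == "tonsil_like":
        cy, cx = rng.uniform(3, n_rows - 4), rng.uniform(3, n_cols - 4)
        follicle = _disc(n_rows, n_cols, cy, cx, min(n_rows, n_cols) / 3)
        yy = np.mgrid[0:n_rows, 0:n_cols][0]
        light = follicle & (yy <= cy)
        dark = follicle & ~light
        crypt = np.zeros(grid, dtype=bool)
        crypt[:, -max(1, n_cols // 5) :] = True
        light &= ~crypt
        dark &= ~crypt
        extra = ~(light | dark | crypt)
        masks = [
            ("gc_light_zone", light, [genes[3]], [abs_[3]]),
            ("gc_dark_zone", dark, [genes[4]], [abs_[4]]),
            ("crypt", crypt, [genes[5]], [abs_[5]]),
            ("extrafollicular", extra, [genes[6]], [abs_[6]]),
        ]
    else:  # skin_like
        epi_rows = max(1, n_rows // 5)
        epidermis = np.zeros(grid, dtype=bool)
        epidermis[:epi_rows, :] = True
        cy = rng.uniform(epi_rows + 1.5, n_rows - 2)
        cx = rng.uniform(1.5, n_cols - 2)
        site = _disc(n_rows, n_cols, cy, cx, min(n_rows, n_cols) / 4) & ~epidermis
        dermis = ~(epidermis | site)
        tph_genes = [g for g in ("LAG3", "PDCD1", "CXCR6") if g in genes]
        tph_abs = [a for a in ("anti-LAG3", "anti-PD-1", "anti-CXCR6") if a in abs_]
        masks = [
            ("epidermis", epidermis, [genes[3]], [abs_[3]]),
            ("injection_site", site, tph_genes, tph_abs),
            ("dermis", dermis, [genes[4]], [abs_[4]]),
        ]

    domains = []
    for name, mask, mg, mp in masks:
        rna, prot = profile(mg, mp)
        domains.append(Domain(name, mask, rna, prot))
    return TissueModel(grid=grid, domains=domains, background_rate=0.05)
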