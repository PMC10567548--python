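"""Self-consistent synthetic fixture sets for tests and demos.

`make_fixtures` writes everything a pipeline run needs — ADT panel TSV,
A/B whitelists, a toy transcriptome FASTA and a demo tissue YAML — sized
either for fast tests (10x10 grid, 20 genes, 30 ADTs) or at full assay
scale (50x50 grid with the 273-plex human and 189-plex mouse cocktail
sizes, nine isotype controls each).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from spatialcite.barcodes import DNA_ALPHABET, generate_fixture_whitelists, write_whitelist
from spatialcite.errors import ConfigError
from spatialcite.panel import ADTPanel, ADTPanelEntry, write_panel
from spatialcite.simulate import default_antibody_names, default_gene_names, make_demo_tissue

HUMAN_PANEL_SIZE = 273
MOUSE_PANEL_SIZE = 189
N_ISOTYPE_CONTROLS = 9


def random_panel(
    n: int,
    seed: int,
    tag_length: int = 15,
    n_isotype: int = 2,
    species: str = "human",
) -> ADTPanel:
    """Panel of `n` antibodies with unique random tags (isotype controls last)."""
    rng = np.random.default_rng(seed)
    tags: list[str] = []
    seen: set[str] = set()
    while len(tags) < n:
        t = "".join(DNA_ALPHABET[i] for i in rng.integers(0, 4, size=tag_length))
        if t not in seen:
            seen.add(t)
            tags.append(t)
    names = default_antibody_names(n, n_isotype=n_isotype)
    entries = [
        ADTPanelEntry(
            antibody_id=name,
            tag_seq=tag,
            is_isotype_control=name.startswith("IsoCtrl"),
            target_species=species,
        )
        for name, tag in zip(names, tags)
    ]
    return ADTPanel(entries)


def random_transcriptome(
    genes: list[str], seed: int, length: int = 300
) -> dict[str, str]:
    """Random transcript per gene (uniform bases; shared 31-mers are
    astronomically unlikely at these sizes)."""
    rng = np.random.default_rng(seed)
    return {
        g: "".join(DNA_ALPHABET[i] for i in rng.integers(0, 4, size=length))
        for g in genes
    }


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


@dataclass
class FixtureSet:
    outdir: Path
    panel: Path
    whitelist_a: Path
    whitelist_b: Path
    transcriptome: Path
    tissue: Path
    mouse_panel: Path | None = None


def make_fixtures(
    outdir: str | Path,
    seed: int = 0,
    scale: str = "small",
    preset: str = "spleen_like",
) -> FixtureSet:
    """Write a self-consistent fixture set under `outdir`.

    scale="small": 10x10 grid, 20 genes, 30 ADTs — loads and runs in
    seconds. scale="full": 50x50 grid with human- (273) and mouse-sized
    (189) panels and 50-entry whitelists.
    """
    if scale not in ("small", "full"):
        raise ConfigError(f"unknown fixture scale {scale!r}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if scale == "small":
        n_wl, grid, n_genes, n_abs, n_iso = 50, (10, 10), 20, 30, 2
    else:
        n_wl, grid, n_genes, n_abs, n_iso = 50, (50, 50), 20, HUMAN_PANEL_SIZE, N_ISOTYPE_CONTROLS

    wl_a, wl_b = generate_fixture_whitelists(n=n_wl, length=8, min_dist=3, seed=seed)
    panel = random_panel(n_abs, seed=seed + 1, n_isotype=n_iso, species="human")
    genes = default_gene_names(n_genes)
    tx = random_transcriptome(genes, seed=seed + 2)
    tissue = make_demo_tissue(
        preset, seed=seed + 3, grid=grid, n_genes=n_genes, n_antibodies=n_abs,
        n_isotype=n_iso,
    )

    paths = FixtureSet(
        outdir=outdir,
        panel=outdir / "panel.tsv",
        whitelist_a=outdir / "whitelist_a.tsv",
        whitelist_b=outdir / "whitelist_b.tsv",
        transcriptome=outdir / "transcriptome.fasta",
        tissue=outdir / "tissue.yaml",
    )
    write_panel(panel, paths.panel)
    write_whitelist(wl_a, paths.whitelist_a)
    write_whitelist(wl_b, paths.whitelist_b)
    write_fasta(tx, paths.transcriptome)
    tissue.to_yaml(paths.tissue)
    if scale == "full":
        mouse = random_panel(
            MOUSE_PANEL_SIZE, seed=seed + 4, n_isotype=N_ISOTYPE_CONTROLS, species="mouse"
        )
        paths.mouse_panel = outdir / "panel_mouse.tsv"
        write_panel(mouse, paths.mouse_panel)
    return paths
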