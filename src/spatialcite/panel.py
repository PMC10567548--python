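"""ADT panel tables: antibody id -> DNA tag sequence.

Each antibody-derived tag (ADT) carries a DNA sequence unique to its
antibody; a panel is the full cocktail applied to the section (e.g. a
273-plex human or 189-plex mouse cocktail, each with nine isotype
controls). Tags within a panel must be unique and equal-length so that
Hamming matching of the Read-1 tag region is well defined.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from spatialcite.barcodes import is_dna
from spatialcite.errors import ConfigError

DEFAULT_TAG_LENGTH = 15

_TRUTHY = {"1", "true", "yes", "y", "t"}
_FALSY = {"0", "false", "no", "n", "f", ""}


@dataclass(frozen=True)
class ADTPanelEntry:
    antibody_id: str
    tag_seq: str
    is_isotype_control: bool = False
    target_species: str | None = None


class ADTPanel:
    """Validated antibody panel.

    Parameters
    ----------
    entries : list of ADTPanelEntry
        At least one entry; unique, equal-length ACGT tag sequences.
    """

    def __init__(self, entries: list[ADTPanelEntry]):
        if not entries:
            raise ConfigError("ADT panel is empty")
        lengths = {len(e.tag_seq) for e in entries}
        if len(lengths) != 1:
            raise ConfigError(f"mixed ADT tag lengths in panel: {sorted(lengths)}")
        seen: dict[str, str] = {}
        for e in entries:
            if not is_dna(e.tag_seq):
                raise ConfigError(
                    f"antibody {e.antibody_id}: tag {e.tag_seq!r} is not ACGT DNA"
                )
            if e.tag_seq in seen:
                raise ConfigError(
                    f"duplicate tag sequence {e.tag_seq} shared by "
                    f"{seen[e.tag_seq]} and {e.antibody_id}"
                )
            seen[e.tag_seq] = e.antibody_id
        ids = [e.antibody_id for e in entries]
        if len(set(ids)) != len(ids):
            raise ConfigError("duplicate antibody_id in panel")
        self.entries = list(entries)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    @property
    def tag_length(self) -> int:
        return len(self.entries[0].tag_seq)

    @property
    def antibody_ids(self) -> list[str]:
        """Feature order of the protein count matrix (panel order)."""
        return [e.antibody_id for e in self.entries]

    @property
    def isotype_controls(self) -> list[str]:
        return [e.antibody_id for e in self.entries if e.is_isotype_control]

    def tag_to_antibody(self) -> dict[str, str]:
        return {e.tag_seq: e.antibody_id for e in self.entries}

    def build_matcher(self, max_hamming: int) -> dict[str, tuple[str | None, int]]:
        """Precompute tag-neighbourhood -> (antibody_id, distance) for O(1)
        per-read tag lookup; sequences tied between two antibodies at the
        minimal distance map to (None, distance)."""
        from spatialcite.barcodes import _neighbourhood

        table: dict[str, tuple[str | None, int]] = {}
        for e in self.entries:
            for mutant, dist in _neighbourhood(e.tag_seq, max_hamming):
                prev = table.get(mutant)
                if prev is None or dist < prev[1]:
                    table[mutant] = (e.antibody_id, dist)
                elif dist == prev[1] and prev[0] != e.antibody_id:
                    table[mutant] = (None, dist)
        return table


def _parse_bool(value, row: int) -> bool:
    s = str(value).strip().lower()
    if s in _TRUTHY:
        return True
    if s in _FALSY or s == "nan":
        return False
    raise ConfigError(f"panel row {row}: cannot parse boolean {value!r}")


def load_panel(path: str | Path) -> ADTPanel:
    """Load an ADT panel from a TSV with columns antibody_id, tag_seq,
    is_isotype_control (optional: target_species)."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"panel file not found: {path}")
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    except pd.errors.EmptyDataError as exc:
        raise ConfigError(f"panel file is empty: {path}") from exc
    required = {"antibody_id", "tag_seq"}
    missing = required - set(df.columns)
    if missing:
        raise ConfigError(f"panel {path} missing column(s): {sorted(missing)}")
    if df.empty:
        raise ConfigError(f"panel file has no rows: {path}")
    entries = []
    for row_num, rec in enumerate(df.itertuples(index=False), start=2):
        tag = str(rec.tag_seq).strip().upper()
        if not is_dna(tag):
            raise ConfigError(f"panel {path} row {row_num}: malformed DNA tag {tag!r}")
        iso = (
            _parse_bool(rec.is_isotype_control, row_num)
            if "is_isotype_control" in df.columns
            else False
        )
        species = (
            str(rec.target_species) if "target_species" in df.columns else None
        )
        entries.append(
            ADTPanelEntry(
                antibody_id=str(rec.antibody_id).strip(),
                tag_seq=tag,
                is_isotype_control=iso,
                target_species=species,
            )
        )
    return ADTPanel(entries)


def write_panel(panel: ADTPanel, path: str | Path) -> None:
    pd.DataFrame(
        {
            "antibody_id": [e.antibody_id for e in panel],
            "tag_seq": [e.tag_seq for e in panel],
            "is_isotype_control": [int(e.is_isotype_control) for e in panel],
        }
    ).to_csv(path, sep="\t", index=False)
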