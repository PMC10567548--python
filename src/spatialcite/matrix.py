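"""Sparse spatial count matrices (features x pixels) and their on-disk forms.

A pixel is addressed by its (row, col) barcode-pair indices and labelled
"{row}x{col}". Matrices are written as MatrixMarket coordinate files with
features.tsv / pixels.tsv sidecars, plus an optional long-form TSV
(row, col, feature, count) mirroring the "spatial locations and expression
levels" table shape used downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from spatialcite.errors import DataError


@dataclass(frozen=True, order=True)
class PixelAddress:
    """1-based (row, col) grid address; row = barcode A index, col = barcode B."""

    row: int
    col: int

    def __post_init__(self) -> None:
        if self.row < 1 or self.col < 1:
            raise DataError(f"pixel address must be 1-based, got ({self.row},{self.col})")

    @property
    def label(self) -> str:
        return f"{self.row}x{self.col}"

    @classmethod
    def from_label(cls, label: str) -> "PixelAddress":
        r, c = label.split("x")
        return cls(int(r), int(c))


class SpatialCountMatrix:
    """Features x pixels sparse integer count matrix for one modality.

    Parameters
    ----------
    modality : {"RNA", "protein"}
    features : list of str
        Fixed feature order (panel order for protein, sorted genes for RNA).
    pixels : list of PixelAddress
        Column order.
    counts : scipy sparse or dense array, shape (n_features, n_pixels)
    """

    def __init__(self, modality, features, pixels, counts):
        if modality not in ("RNA", "protein"):
            raise DataError(f"modality must be RNA or protein, got {modality!r}")
        counts = sp.csr_matrix(counts, dtype=np.int64)
        if counts.shape != (len(features), len(pixels)):
            raise DataError(
                f"counts shape {counts.shape} != ({len(features)}, {len(pixels)})"
            )
        if counts.nnz and counts.data.min() < 0:
            raise DataError("negative counts")
        if len(set(features)) != len(features):
            raise DataError("duplicate feature ids")
        if len(set(pixels)) != len(pixels):
            raise DataError("duplicate pixel addresses")
        self.modality = modality
        self.features = list(features)
        self.pixels = list(pixels)
        self.counts = counts

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    @property
    def pixel_labels(self) -> list[str]:
        return [p.label for p in self.pixels]

    def to_dense(self) -> np.ndarray:
        return self.counts.toarray()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.to_dense(), index=self.features, columns=self.pixel_labels
        )

    def pixel_totals(self) -> np.ndarray:
        """Total UMI count per pixel (column sums)."""
        return np.asarray(self.counts.sum(axis=0)).ravel()

    def feature_totals(self) -> np.ndarray:
        return np.asarray(self.counts.sum(axis=1)).ravel()

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, SpatialCountMatrix)
            and self.modality == other.modality
            and self.features == other.features
            and self.pixels == other.pixels
            and (self.counts != other.counts).nnz == 0
        )

    def to_anndata(self):
        """Pixels x features AnnData with spatial coordinates in .obsm."""
        import anndata

        ad = anndata.AnnData(
            X=self.counts.T.tocsr().astype(np.float32),
            obs=pd.DataFrame(
                {
                    "row": [p.row for p in self.pixels],
                    "col": [p.col for p in self.pixels],
                },
                index=self.pixel_labels,
            ),
            var=pd.DataFrame(index=self.features),
        )
        ad.obsm["spatial"] = ad.obs[["row", "col"]].to_numpy(float)
        return ad

    # ---- persistence -------------------------------------------------

    def write_mtx(self, outdir: str | Path, prefix: str = "") -> None:
        """Write matrix.mtx + features.tsv + pixels.tsv (atomically)."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        mtx = outdir / f"{prefix}matrix.mtx"
        tmp = outdir / f".{prefix}matrix.mtx.tmp"
        with open(tmp, "wb") as fh:  # write-then-rename: no truncated matrices
            scipy.io.mmwrite(fh, self.counts.tocoo(), field="integer")
        tmp.replace(mtx)
        pd.Series(self.features).to_csv(
            outdir / f"{prefix}features.tsv", sep="\t", index=False, header=False
        )
        pd.DataFrame(
            {
                "label": self.pixel_labels,
                "row": [p.row for p in self.pixels],
                "col": [p.col for p in self.pixels],
            }
        ).to_csv(outdir / f"{prefix}pixels.tsv", sep="\t", index=False)

    @classmethod
    def read_mtx(cls, outdir: str | Path, modality: str, prefix: str = ""):
        outdir = Path(outdir)
        counts = scipy.io.mmread(str(outdir / f"{prefix}matrix.mtx"))
        features = (
            pd.read_csv(outdir / f"{prefix}features.tsv", sep="\t", header=None)[0]
            .astype(str)
            .tolist()
        )
        px = pd.read_csv(outdir / f"{prefix}pixels.tsv", sep="\t")
        pixels = [PixelAddress(int(r), int(c)) for r, c in zip(px["row"], px["col"])]
        return cls(modality, features, pixels, counts)

    def write_long_tsv(self, path: str | Path) -> None:
        """Long-form (row, col, feature, count) table of nonzero entries."""
        coo = self.counts.tocoo()
        df = pd.DataFrame(
            {
                "row": [self.pixels[j].row for j in coo.col],
                "col": [self.pixels[j].col for j in coo.col],
                "feature": [self.features[i] for i in coo.row],
                "count": coo.data,
            }
        ).sort_values(["row", "col", "feature"], kind="mergesort")
        df.to_csv(path, sep="\t", index=False)
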