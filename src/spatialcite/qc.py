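"""Per-pixel QC, CLR / log normalization, signature scoring, pseudo-bulk.

Protein (ADT) counts are compositional — the cocktail competes for a
fixed capture capacity per pixel — so they are normalized with the
centered log-ratio transform, y_fp = ln(x_fp + 1) - mean_f ln(x_fp + 1),
the standard ADT treatment. RNA gets simple library-size log
normalization (a deliberate, lighter stand-in for variance-stabilizing
transforms handled by downstream tools). Signature scores (e.g. the Tph
score over LAG3 / PDCD1 / CXCR6) are the per-pixel mean of gene z-scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from spatialcite.errors import ConfigError, DataError
from spatialcite.matrix import PixelAddress, SpatialCountMatrix


@dataclass
class PixelQC:
    pixel: PixelAddress
    umi_count: int
    feature_count: int
    modality: str


@dataclass
class QCSummary:
    n_pixels: int
    mean_umi_count: float
    mean_feature_count: float
    modality: str

    def as_dict(self) -> dict:
        return dict(self.__dict__)


class NormalizedMatrix:
    """Dense real-valued features x pixels matrix plus its method tag."""

    def __init__(self, modality, features, pixels, values: np.ndarray, method: str):
        values = np.asarray(values, dtype=float)
        if values.shape != (len(features), len(pixels)):
            raise DataError("normalized value shape mismatch")
        self.modality = modality
        self.features = list(features)
        self.pixels = list(pixels)
        self.values = values
        self.method = method

    @property
    def pixel_labels(self) -> list[str]:
        return [p.label for p in self.pixels]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.features, columns=self.pixel_labels)

    def write_mtx(self, outdir, prefix: str = "") -> None:
        """matrix.mtx (real general) + features/pixels sidecars + method JSON."""
        import json
        from pathlib import Path

        import scipy.io
        import scipy.sparse as sp

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        scipy.io.mmwrite(
            str(outdir / f"{prefix}matrix.mtx"), sp.coo_matrix(self.values), field="real"
        )
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
        (outdir / f"{prefix}method.json").write_text(
            json.dumps({"method": self.method, "modality": self.modality})
        )


def qc_metrics(m: SpatialCountMatrix) -> tuple[list[PixelQC], QCSummary]:
    """Per-pixel total UMI and detected-feature counts plus their means.

    umi_count is the pixel's column sum; feature_count is the number of
    features with >=1 UMI in that pixel (protein count / gene count).
    """
    dense = m.counts
    umi = np.asarray(dense.sum(axis=0)).ravel()
    nnz = np.asarray((dense > 0).sum(axis=0)).ravel()
    per_pixel = [
        PixelQC(p, int(u), int(f), m.modality)
        for p, u, f in zip(m.pixels, umi, nnz)
    ]
    n = len(m.pixels)
    summary = QCSummary(
        n_pixels=n,
        mean_umi_count=float(umi.mean()) if n else 0.0,
        mean_feature_count=float(nnz.mean()) if n else 0.0,
        modality=m.modality,
    )
    return per_pixel, summary


def clr_normalize(m: SpatialCountMatrix, margin: str = "per_pixel") -> NormalizedMatrix:
    """Centered log-ratio transform with a +1 pseudocount (natural log).

    per_pixel (default): center ln(x+1) across all features within each
    pixel, so each pixel's values sum to zero. per_feature: the transpose
    convention (center across pixels within each feature).
    """
    if margin not in ("per_pixel", "per_feature"):
        raise ConfigError(f"unknown CLR margin {margin!r}")
    if m.shape[0] == 0 or m.shape[1] == 0:
        raise DataError("cannot CLR-normalize an empty matrix")
    logx = np.log1p(m.to_dense().astype(float))
    axis = 0 if margin == "per_pixel" else 1
    centered = logx - logx.mean(axis=axis, keepdims=True)
    return NormalizedMatrix(m.modality, m.features, m.pixels, centered, "CLR")


def lognorm_rna(m: SpatialCountMatrix, scale: float = 10_000.0) -> NormalizedMatrix:
    """Library-size log normalization: y = ln(1 + scale * x / pixel_total).

    All-zero pixels map to zeros (no division error).
    """
    if scale <= 0:
        raise ConfigError(f"scale must be positive, got {scale}")
    x = m.to_dense().astype(float)
    totals = x.sum(axis=0, keepdims=True)
    safe = np.where(totals > 0, totals, 1.0)
    return NormalizedMatrix(
        m.modality, m.features, m.pixels, np.log1p(scale * x / safe), "lognorm"
    )


@dataclass
class SignatureScore:
    scores: pd.Series  # index: pixel labels
    genes_used: list[str]
    genes_missing: list[str]
    genes_constant: list[str]
    method: str = "mean_z"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"pixel": self.scores.index, "score": self.scores.values})


def signature_score(
    nm: NormalizedMatrix, genes: list[str], method: str = "mean_z"
) -> SignatureScore:
    """Per-pixel signature score: mean of per-gene z-scores across pixels.

    Listed genes are deduplicated (order-insensitive); genes absent from
    the matrix are skipped and reported, as are zero-variance genes
    (which carry no ranking information). At least one listed gene must
    be present and variable.
    """
    if method != "mean_z":
        raise ConfigError(f"unknown scoring method {method!r}")
    wanted = sorted(set(genes))
    present = [g for g in wanted if g in nm.features]
    missing = [g for g in wanted if g not in nm.features]
    if not present:
        raise DataError(f"none of the signature genes {wanted} are in the matrix")
    idx = [nm.features.index(g) for g in present]
    vals = nm.values[idx, :]
    sd = vals.std(axis=1, ddof=0)
    keep = sd > 0
    constant = [g for g, k in zip(present, keep) if not k]
    used = [g for g, k in zip(present, keep) if k]
    if not used:
        raise DataError("all present signature genes are constant across pixels")
    z = (vals[keep] - vals[keep].mean(axis=1, keepdims=True)) / sd[keep, None]
    scores = pd.Series(z.mean(axis=0), index=nm.pixel_labels)
    return SignatureScore(scores, used, missing, constant)


def pseudobulk(
    m: SpatialCountMatrix, min_total_umi: int = 10
) -> pd.DataFrame:
    """Aggregate pixels into one bulk profile per feature.

    Pixels with total UMI below `min_total_umi` are excluded before
    summing (mirroring the low-count cell filter used when comparing
    against dissociated single-cell profiles). Returns per-feature raw
    totals and CLR-transformed totals, for correlation against an
    external reference profile.
    """
    totals_per_pixel = m.pixel_totals()
    keep = totals_per_pixel >= min_total_umi
    sub = m.counts[:, np.nonzero(keep)[0]]
    feature_totals = np.asarray(sub.sum(axis=1), dtype=float).ravel()
    log_tot = np.log1p(feature_totals)
    clr = log_tot - log_tot.mean()
    return pd.DataFrame(
        {"feature": m.features, "total": feature_totals.astype(int), "clr": clr}
    ).set_index("feature")
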