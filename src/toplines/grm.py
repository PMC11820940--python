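"""Genomic relationship matrix (VanRaden method 1).

G = WW' / (2 * sum_j p_j (1 - p_j)) with W the dosage matrix centered at
twice the observed allele frequency of each marker.  Monomorphic markers
contribute zero to the numerator and are excluded from the denominator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import MarkerMatrix

__all__ = ["GenomicRelationship", "impute_markers", "compute_grm", "stabilize"]

SYMMETRY_TOL = 1e-10
PSD_TOL = -1e-8


@dataclass
class GenomicRelationship:
    """Symmetric n x n relationship kernel with its line ordering."""

    line_ids: list[str]
    G: np.ndarray

    def __post_init__(self) -> None:
        self.G = np.asarray(self.G, dtype=float)
        n = len(self.line_ids)
        if self.G.shape != (n, n):
            raise ValueError("G shape does not match number of line_ids")
        if not np.allclose(self.G, self.G.T, atol=SYMMETRY_TOL, rtol=0):
            raise ValueError("G is not symmetric")
        self.G = (self.G + self.G.T) / 2.0

    def min_eigenvalue(self) -> float:
        return float(np.linalg.eigvalsh(self.G)[0])

    def index_of(self, line_ids: list[str]) -> np.ndarray:
        pos = {lid: i for i, lid in enumerate(self.line_ids)}
        return np.array([pos[lid] for lid in line_ids], dtype=int)


def impute_markers(m: MarkerMatrix) -> MarkerMatrix:
    """Replace each missing dosage by its marker's mean over observed lines."""
    dosages = m.dosages.copy()
    mask = np.isnan(dosages)
    if not mask.any():
        return MarkerMatrix(list(m.line_ids), list(m.marker_ids), dosages)
    all_missing = mask.all(axis=0)
    if all_missing.any():
        j = int(np.flatnonzero(all_missing)[0])
        raise ValueError(f"marker {m.marker_ids[j]!r} is missing for every line")
    col_means = np.nanmean(dosages, axis=0)
    dosages[mask] = np.broadcast_to(col_means, dosages.shape)[mask]
    return MarkerMatrix(list(m.line_ids), list(m.marker_ids), dosages)


def compute_grm(m: MarkerMatrix) -> GenomicRelationship:
    """VanRaden G from an imputed marker matrix.

    Allele frequencies are estimated from all lines present (train and test
    together), giving a single G per dataset.
    """
    M = m.dosages
    if np.isnan(M).any():
        raise ValueError("marker matrix has missing entries; impute first")
    n, p_markers = M.shape
    if n < 2:
        raise ValueError("need at least 2 lines")
    p = M.mean(axis=0) / 2.0
    poly = (p > 0.0) & (p < 1.0)
    denom = 2.0 * np.sum(p[poly] * (1.0 - p[poly]))
    if denom <= 0.0:
        raise ValueError("all markers monomorphic: VanRaden denominator is zero")
    W = M - 2.0 * p  # monomorphic columns center to exactly zero
    G = (W @ W.T) / denom
    G = (G + G.T) / 2.0
    return GenomicRelationship(list(m.line_ids), G)


def stabilize(grm: GenomicRelationship, ridge: float = 1e-6) -> GenomicRelationship:
    """Add ridge * I so eigen/Cholesky decompositions are numerically safe."""
    if ridge < 0:
        raise ValueError("ridge must be non-negative")
    if ridge == 0.0:
        return GenomicRelationship(list(grm.line_ids), grm.G.copy())
    G = grm.G + ridge * np.eye(len(grm.line_ids))
    return GenomicRelationship(list(grm.line_ids), G)
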