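"""Membrane frame estimation and stromal/lumenal leaflet assignment.

The thylakoid membrane plane is the plane of maximal chlorophyll spread:
the membrane normal is the eigenvector of the chlorophyll-Mg covariance
matrix with the smallest eigenvalue.  Chlorophyll Mg atoms in such
complexes sit in two roughly parallel layers, one per leaflet; projecting
them onto the normal and splitting the 1-D projections with a deterministic
two-means gives the midplane.  The normal's sign is chosen so that a
stromal reference point (by default the Fe4S4 cluster centroid, which sits
on the stromal side of photosystem I) projects positive.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from .exceptions import ConfigError, DegenerateLeafletError, InsufficientDataError
from .structure_io import (
    Leaflet,
    PigmentRecord,
    StructureModel,
)

#: Minimum chlorophyll count for a covariance-based frame.
MIN_CHLOROPHYLLS = 10
#: Leaflet cluster centers closer than this (Angstrom) are degenerate.
MIN_LEAFLET_SEPARATION = 5.0
#: Chlorophylls within this distance of the midplane are flagged uncertain.
MIDPLANE_MARGIN = 3.0

#: Residue names of iron-sulfur clusters usable as a stromal reference.
FES_RESIDUE_NAMES = {"SF4", "F3S", "FES"}


@dataclass(frozen=True)
class MembraneFrame:
    """Unit membrane normal (stromal-pointing), origin, and midplane offset.

    Projections are taken relative to ``origin``; a chlorophyll is stromal
    iff its projection exceeds ``midplane_offset``.
    """

    normal: np.ndarray
    midplane_offset: float
    origin: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "normal", np.asarray(self.normal, dtype=float))
        object.__setattr__(self, "origin", np.asarray(self.origin, dtype=float))
        if abs(np.linalg.norm(self.normal) - 1.0) > 1e-9:
            raise ValueError("membrane normal must be a unit vector")

    def project(self, points: np.ndarray) -> np.ndarray:
        points = np.asarray(points, dtype=float)
        return (points - self.origin) @ self.normal

    def side(self, point: np.ndarray) -> Leaflet:
        return (Leaflet.STROMAL if self.project(point) > self.midplane_offset
                else Leaflet.LUMENAL)

    def to_dict(self) -> dict:
        return {
            "normal": [float(c) for c in self.normal],
            "origin": [float(c) for c in self.origin],
            "midplane_offset": float(self.midplane_offset),
        }


def _two_means_1d(values: np.ndarray, max_iter: int = 100) -> tuple[float, float]:
    """Deterministic 1-D 2-means: centers start at the 25th/75th percentiles."""
    lo, hi = np.percentile(values, [25.0, 75.0])
    if lo == hi:
        return float(lo), float(hi)
    for _ in range(max_iter):
        assign_hi = np.abs(values - hi) < np.abs(values - lo)
        if not assign_hi.any() or assign_hi.all():
            break
        new_lo = float(values[~assign_hi].mean())
        new_hi = float(values[assign_hi].mean())
        if new_lo == lo and new_hi == hi:
            break
        lo, hi = new_lo, new_hi
    return float(min(lo, hi)), float(max(lo, hi))


def stromal_reference_from_fes(model: StructureModel) -> Optional[np.ndarray]:
    """Centroid of iron-sulfur cluster atoms, if any are present."""
    coords = [a.position for a in model.atoms if a.residue_name in FES_RESIDUE_NAMES]
    if not coords:
        return None
    return np.mean(np.asarray(coords, dtype=float), axis=0)


def estimate_frame(pigments: Iterable[PigmentRecord],
                   stromal_reference: Optional[Sequence[float]] = None,
                   ) -> MembraneFrame:
    """Fit the membrane frame to the chlorophyll Mg cloud.

    Raises :class:`InsufficientDataError` below 10 chlorophylls and
    :class:`DegenerateLeafletError` when the projected cloud is unimodal
    (cluster centers closer than 5 Angstrom).  ``stromal_reference`` is a
    point known to lie on the stromal side; it is required because the
    covariance normal has no intrinsic sign.
    """
    points = np.array([p.representative_point for p in pigments
                       if p.is_chlorophyll], dtype=float)
    if len(points) < MIN_CHLOROPHYLLS:
        raise InsufficientDataError(
            f"need at least {MIN_CHLOROPHYLLS} chlorophylls to estimate the "
            f"membrane frame, got {len(points)}")
    if stromal_reference is None:
        raise ConfigError(
            "no stromal reference: supply one explicitly or parse a model "
            "containing Fe4S4 clusters (stromal_reference_from_fes)")
    origin = points.mean(axis=0)
    cov = np.cov((points - origin).T)
    eigvals, eigvecs = np.linalg.eigh(cov)
    normal = eigvecs[:, np.argmin(eigvals)]
    normal = normal / np.linalg.norm(normal)
    ref = np.asarray(stromal_reference, dtype=float)
    if (ref - origin) @ normal < 0:
        normal = -normal
    projections = (points - origin) @ normal
    lo, hi = _two_means_1d(projections)
    if hi - lo < MIN_LEAFLET_SEPARATION:
        raise DegenerateLeafletError(
            f"projected chlorophyll clusters separated by only {hi - lo:.2f} A "
            f"(< {MIN_LEAFLET_SEPARATION} A); cannot split leaflets")
    return MembraneFrame(normal=normal, midplane_offset=(lo + hi) / 2.0,
                         origin=origin)


def assign_leaflets(model: StructureModel, frame: MembraneFrame,
                    midplane_margin: float = MIDPLANE_MARGIN) -> StructureModel:
    """Set the leaflet on every pigment of ``model`` (in place; returns it).

    Chlorophylls are stromal iff their Mg projection exceeds the midplane
    offset; those within ``midplane_margin`` of the midplane are flagged
    ``near_midplane`` rather than silently forced.  Carotenoids (and other
    pigments) inherit the leaflet of their nearest chlorophyll.
    """
    chls = model.chlorophylls()
    for p in chls:
        t = float(frame.project(p.representative_point))
        p.leaflet = (Leaflet.STROMAL if t > frame.midplane_offset
                     else Leaflet.LUMENAL)
        p.near_midplane = abs(t - frame.midplane_offset) < midplane_margin
    if chls:
        chl_points = np.array([p.representative_point for p in chls])
        for p in model.pigments:
            if p.is_chlorophyll:
                continue
            d = np.linalg.norm(chl_points - p.representative_point, axis=1)
            p.leaflet = chls[int(np.argmin(d))].leaflet
    return model
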