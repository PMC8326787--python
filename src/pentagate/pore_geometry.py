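"""Channel axis estimation, pore radius profiles, gate radius, hydration.

The fivefold (C5) axis is not part of any deposited record, so it is
estimated as the total-least-squares line through the per-residue centroids
of the pore-lining C-alpha rings (default M2 residues 222-247).  All radii
are centre distances to atom positions — no van-der-Waals subtraction —
matching the convention of C-alpha/C-beta pore profiles.

Prime notation maps M2 residue numbers onto the family-wide pore register:
residue 233 is the 9' hydrophobic gate, i.e. ``prime = residue - 224``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .errors import GeometryError, SelectionError
from .structure_io import (
    PentamerModel,
    Selection,
    TrajectoryFrameSet,
    chain_atom_indices,
)

#: Default pore-lining residue range (M2 helix).
DEFAULT_LINING_RANGE = (222, 247)
#: Default ECD range used to orient the axis (+direction toward the ECD).
DEFAULT_ECD_RANGE = (20, 190)
#: Default radial cutoff for counting pore waters, Angstrom.
DEFAULT_HYDRATION_RADIAL_CUTOFF = 6.0

M2_PRIME_OFFSET = 224


@dataclass(frozen=True)
class PoreAxis:
    """The channel axis: a point on the line and a unit direction.

    The direction is oriented so the extracellular domain lies on the
    positive side (``+z`` in the usual membrane frame).
    """

    point: np.ndarray
    direction: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.direction, dtype=float)
        n = np.linalg.norm(d)
        if not np.isfinite(n) or n < 1e-12:
            raise GeometryError("axis direction has zero length")
        object.__setattr__(self, "direction", d / n)
        object.__setattr__(self, "point", np.asarray(self.point, dtype=float))

    def axial(self, coords: np.ndarray) -> np.ndarray:
        """Signed axial coordinate(s) of points along the axis."""
        return (np.atleast_2d(coords) - self.point) @ self.direction

    def radial(self, coords: np.ndarray) -> np.ndarray:
        """Perpendicular distance(s) of points to the axis."""
        rel = np.atleast_2d(coords) - self.point
        axial = rel @ self.direction
        perp = rel - np.outer(axial, self.direction)
        return np.linalg.norm(perp, axis=1)

    def perpendicular_basis(self) -> tuple[np.ndarray, np.ndarray]:
        """Orthonormal (u, v) spanning the plane perpendicular to the axis,
        with (u, v, direction) right-handed."""
        d = self.direction
        seed = np.array([1.0, 0.0, 0.0])
        if abs(d @ seed) > 0.9:
            seed = np.array([0.0, 1.0, 0.0])
        u = seed - (seed @ d) * d
        u /= np.linalg.norm(u)
        v = np.cross(d, u)
        return u, v


def estimate_pore_axis(
    model: PentamerModel,
    lining_sel: Selection | None = None,
    ecd_sel: Selection | None = None,
) -> PoreAxis:
    """Total-least-squares line through symmetric pore-lining ring centroids.

    Each residue of ``lining_sel`` present in all five chains contributes the
    centroid of its five C-alpha atoms; the best-fit line through these
    centroids (first principal direction) is the axis.  Oriented so the
    centroid of ``ecd_sel`` (default C-alpha 20-190) projects positively.
    """
    if lining_sel is None:
        lining_sel = Selection.ca(DEFAULT_LINING_RANGE)
    if ecd_sel is None:
        ecd_sel = Selection.ca(DEFAULT_ECD_RANGE)
    per_chain = chain_atom_indices(model, lining_sel, symmetric="drop")
    if len(per_chain) != 5:
        raise SelectionError("lining selection must resolve on all five chains")
    coords = model.coord
    stacks = np.stack([coords[idx] for idx in per_chain.values()])  # (5, R, 3)
    centroids = stacks.mean(axis=0)  # (R, 3)
    if centroids.shape[0] < 2:
        raise GeometryError(
            f"axis undetermined: only {centroids.shape[0]} symmetric ring(s)"
        )
    mean = centroids.mean(axis=0)
    _, _, vt = np.linalg.svd(centroids - mean)
    direction = vt[0]
    try:
        from .structure_io import resolve_selection

        ecd_idx = resolve_selection(model, ecd_sel)
        ecd_centroid = coords[ecd_idx].mean(axis=0)
    except SelectionError:
        ecd_centroid = coords[model.protein_mask].mean(axis=0)
    if (ecd_centroid - mean) @ direction < 0:
        direction = -direction
    return PoreAxis(mean, direction)


def residue_prime(residue_number: int) -> int:
    """Prime index of an M2 residue (233 -> 9', 237 -> 13')."""
    if not (DEFAULT_LINING_RANGE[0] <= residue_number <= DEFAULT_LINING_RANGE[1]):
        raise ValueError(
            f"residue {residue_number} outside M2 prime-notation range "
            f"{DEFAULT_LINING_RANGE[0]}-{DEFAULT_LINING_RANGE[1]}"
        )
    return residue_number - M2_PRIME_OFFSET


class PoreProfileEntry(NamedTuple):
    residue_number: int
    prime_index: int | None
    z: float
    radius: float
    atom_name: str


@dataclass
class PoreProfile:
    """Per-residue pore radii ordered by axial coordinate."""

    entries: list[PoreProfileEntry]

    def __post_init__(self) -> None:
        self.entries = sorted(self.entries, key=lambda e: e.z)

    def radius_of(self, residue_number: int) -> float:
        for e in self.entries:
            if e.residue_number == residue_number:
                return e.radius
        raise KeyError(residue_number)

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.entries)


def pore_profile(
    model: PentamerModel,
    axis: PoreAxis,
    residues: tuple[int, int] = DEFAULT_LINING_RANGE,
    atom_name: str = "CA",
) -> PoreProfile:
    """Mean perpendicular ring distance to the axis, per residue.

    A residue missing the named atom in more than one chain is excluded with
    a warning; an entirely empty profile raises :class:`SelectionError`.
    """
    a = model.atoms
    entries: list[PoreProfileEntry] = []
    lo, hi = residues
    for res in range(lo, hi + 1):
        mask = (
            model.protein_mask
            & (a.res_id == res)
            & (a.atom_name == atom_name)
        )
        n = int(mask.sum())
        if n < 4:
            if n > 0 or res in a.res_id[model.protein_mask]:
                warnings.warn(
                    f"residue {res}: atom {atom_name} present in {n}/5 chains; "
                    f"excluded from profile", stacklevel=2
                )
            continue
        coords = model.coord[mask]
        radius = float(axis.radial(coords).mean())
        z = float(axis.axial(coords).mean())
        try:
            prime = residue_prime(res)
        except ValueError:
            prime = None
        entries.append(PoreProfileEntry(res, prime, z, radius, atom_name))
    if not entries:
        raise SelectionError(
            f"no residue in {lo}-{hi} has atom {atom_name} in >= 4 chains"
        )
    return PoreProfile(entries)


def gate_radius(
    model: PentamerModel,
    axis: PoreAxis,
    residue: int = 233,
    atom_name: str = "CB",
) -> float:
    """Mean distance of the five gate atoms to the axis (default I233 C-beta,
    the 9' hydrophobic gate)."""
    a = model.atoms
    mask = (
        model.protein_mask & (a.res_id == residue) & (a.atom_name == atom_name)
    )
    if int(mask.sum()) != 5:
        raise GeometryError(
            f"incomplete ring: residue {residue} atom {atom_name} present in "
            f"{int(mask.sum())}/5 chains"
        )
    return float(axis.radial(model.coord[mask]).mean())


def _ring_z(
    model: PentamerModel, axis: PoreAxis, residue: int,
    xyz: np.ndarray | None = None,
) -> float:
    a = model.atoms
    mask = model.protein_mask & (a.res_id == residue) & (a.atom_name == "CA")
    if not np.any(mask):
        raise SelectionError(f"residue {residue} has no CA atoms")
    if xyz is None:
        xyz = model.coord
    return float(axis.axial(xyz[mask].mean(axis=0))[0])


def water_occupancy(
    model: PentamerModel,
    axis: PoreAxis,
    lower_residue: int = 233,
    upper_residue: int = 237,
    radial_cutoff: float = DEFAULT_HYDRATION_RADIAL_CUTOFF,
    coords: np.ndarray | None = None,
) -> int:
    """Number of water oxygens inside the gate cylinder.

    Counts water oxygens whose axial coordinate lies in the closed interval
    between the C-alpha ring centroids of the two bounding residues (default
    I233/9' and A237/13') and whose perpendicular distance to the axis is at
    most ``radial_cutoff``.  ``coords`` optionally overrides the model's
    coordinate array (same atom order), for per-frame evaluation.
    """
    a = model.atoms
    water = model.water_mask & np.char.startswith(
        a.atom_name.astype(str), "O"
    )
    if not np.any(water):
        warnings.warn("no water oxygens in topology; occupancy is 0", stacklevel=2)
        return 0
    xyz = model.coord if coords is None else np.asarray(coords, dtype=float)
    # ring bounds must come from the same coordinate set
    z1 = _ring_z(model, axis, lower_residue, xyz)
    z2 = _ring_z(model, axis, upper_residue, xyz)
    zlo, zhi = min(z1, z2), max(z1, z2)
    wz = axis.axial(xyz[water]).ravel()
    wr = axis.radial(xyz[water])
    inside = (wz >= zlo) & (wz <= zhi) & (wr <= radial_cutoff)
    return int(inside.sum())


def water_occupancy_series(
    traj: TrajectoryFrameSet,
    lower_residue: int = 233,
    upper_residue: int = 237,
    radial_cutoff: float = DEFAULT_HYDRATION_RADIAL_CUTOFF,
    lining_sel: Selection | None = None,
) -> np.ndarray:
    """Per-frame pore water counts; the axis is re-estimated each frame."""
    out = np.empty(traj.n_frames, dtype=int)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i in range(traj.n_frames):
            frame = traj.frame_model(i)
            axis = estimate_pore_axis(frame, lining_sel)
            out[i] = water_occupancy(
                frame, axis, lower_residue, upper_residue, radial_cutoff
            )
    return out
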