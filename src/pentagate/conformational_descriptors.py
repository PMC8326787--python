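"""Quaternary gating descriptors: ECD spread and domain twist.

Spread is the radius of gyration of extracellular C-alpha atoms about the
channel axis (default residues 20-190): ``sqrt(mean r_perp^2)`` with unit
weights.  A contracted ECD gives a smaller spread.

Twist is the average dihedral angle through four centres of mass —
(single-subunit ECD, full ECD, full TMD, same-subunit TMD) — measuring the
rotation of the extracellular ring relative to the transmembrane ring.
Dihedrals follow the IUPAC sign convention and are averaged circularly over
the five subunits to avoid +-180 degree wraparound.  COMs use C-alpha atoms
with unit weights, consistent with every other descriptor here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import GeometryError, SelectionError
from .pore_geometry import PoreAxis, estimate_pore_axis
from .structure_io import (
    PentamerModel,
    Selection,
    TrajectoryFrameSet,
    chain_atom_indices,
    resolve_selection,
)

DEFAULT_SPREAD_RANGE = (20, 190)
DEFAULT_TWIST_ECD_RANGE = (20, 190)
DEFAULT_TWIST_TMD_RANGE = (197, 313)


def ecd_spread(
    model: PentamerModel,
    axis: PoreAxis | None = None,
    sel: Selection | None = None,
    coords: np.ndarray | None = None,
) -> float:
    """Radius of gyration about the channel axis over the selection."""
    if sel is None:
        sel = Selection.ca(DEFAULT_SPREAD_RANGE)
    if axis is None:
        axis = estimate_pore_axis(model)
    idx = resolve_selection(model, sel)
    xyz = model.coord if coords is None else np.asarray(coords, dtype=float)
    r = axis.radial(xyz[idx])
    return float(np.sqrt(np.mean(r**2)))


def dihedral(p1: np.ndarray, p2: np.ndarray, p3: np.ndarray, p4: np.ndarray) -> float:
    """Signed dihedral angle (degrees, IUPAC convention) of four points."""
    b1 = np.asarray(p2, float) - np.asarray(p1, float)
    b2 = np.asarray(p3, float) - np.asarray(p2, float)
    b3 = np.asarray(p4, float) - np.asarray(p3, float)
    n2 = np.linalg.norm(b2)
    if n2 < 1e-9:
        raise GeometryError("undefined dihedral: central points coincide")
    c1 = np.cross(b1, b2)
    c2 = np.cross(b2, b3)
    if np.linalg.norm(c1) < 1e-12 or np.linalg.norm(c2) < 1e-12:
        raise GeometryError("undefined dihedral: collinear points")
    x = c1 @ c2
    y = np.cross(c1, c2) @ (b2 / n2)
    return float(np.degrees(np.arctan2(y, x)))


def domain_twist(
    model: PentamerModel,
    ecd_sel: Selection | None = None,
    tmd_sel: Selection | None = None,
    coords: np.ndarray | None = None,
    return_per_subunit: bool = False,
):
    """Average four-COM dihedral between the ECD and TMD rings, degrees.

    For each subunit i the dihedral (ECD_i COM, full-ECD COM, full-TMD COM,
    TMD_i COM) is computed; the circular mean over the five subunits is
    returned in (-180, 180].
    """
    if ecd_sel is None:
        ecd_sel = Selection.ca(DEFAULT_TWIST_ECD_RANGE)
    if tmd_sel is None:
        tmd_sel = Selection.ca(DEFAULT_TWIST_TMD_RANGE)
    xyz = model.coord if coords is None else np.asarray(coords, dtype=float)
    ecd_chains = chain_atom_indices(model, ecd_sel)
    tmd_chains = chain_atom_indices(model, tmd_sel)
    if set(ecd_chains) != set(model.chains) or set(tmd_chains) != set(model.chains):
        raise SelectionError("twist selections must resolve on all five chains")
    ecd_all = xyz[np.concatenate(list(ecd_chains.values()))].mean(axis=0)
    tmd_all = xyz[np.concatenate(list(tmd_chains.values()))].mean(axis=0)
    per_subunit = np.array([
        dihedral(
            xyz[ecd_chains[c]].mean(axis=0),
            ecd_all,
            tmd_all,
            xyz[tmd_chains[c]].mean(axis=0),
        )
        for c in model.chains
    ])
    rad = np.radians(per_subunit)
    mean = float(np.degrees(np.arctan2(np.mean(np.sin(rad)), np.mean(np.cos(rad)))))
    if mean <= -180.0:
        mean += 360.0
    if return_per_subunit:
        return mean, per_subunit
    return mean


@dataclass
class DescriptorSeries:
    """Per-frame quaternary descriptors."""

    frame_times: np.ndarray   # ns
    spread: np.ndarray        # Angstrom
    twist: np.ndarray         # degrees, (-180, 180]

    def __post_init__(self) -> None:
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        self.spread = np.asarray(self.spread, dtype=float)
        self.twist = np.asarray(self.twist, dtype=float)
        if not (len(self.frame_times) == len(self.spread) == len(self.twist)):
            raise ValueError("series lengths differ")
        if np.any(self.spread < 0):
            raise ValueError("spread must be non-negative")

    def summary(self, level: float = 0.95, n_boot: int = 10_000, seed: int | None = None):
        """Bootstrap median summaries of both descriptors."""
        from .interaction_analysis import bootstrap_median_ci

        return {
            "spread": bootstrap_median_ci(self.spread, level, n_boot, seed),
            "twist": bootstrap_median_ci(self.twist, level, n_boot, seed),
        }


def descriptor_series(
    traj: TrajectoryFrameSet,
    spread_sel: Selection | None = None,
    ecd_sel: Selection | None = None,
    tmd_sel: Selection | None = None,
    lining_sel: Selection | None = None,
) -> DescriptorSeries:
    """Spread and twist per frame; the axis is re-estimated every frame so
    the descriptors track the instantaneous assembly."""
    spread = np.empty(traj.n_frames)
    twist = np.empty(traj.n_frames)
    for i in range(traj.n_frames):
        frame = traj.frame_model(i)
        axis = estimate_pore_axis(frame, lining_sel)
        spread[i] = ecd_spread(frame, axis, spread_sel)
        twist[i] = domain_twist(frame, ecd_sel, tmd_sel)
    return DescriptorSeries(traj.times, spread, twist)
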