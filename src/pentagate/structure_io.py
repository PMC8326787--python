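"""Coordinate model I/O, atom selections, and pentamer subunit ordering.

The universal input is a :class:`PentamerModel`: a five-chain atomic model in
author residue numbering, held as a :class:`biotite.structure.AtomArray`
(coordinates in Angstrom).  Waters and monovalent cations are retained as
labelled heteroatoms; every analysis selection resolves against the protein
chains only unless stated otherwise.

Trajectories (DCD/XTC/TRR frame sets bound to a PDB topology) are exposed as
:class:`TrajectoryFrameSet`, read and written through mdtraj.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import biotite.structure as bst
from biotite.structure.io.pdb import PDBFile

from .errors import (
    AssemblyError,
    AsymmetryError,
    FormatError,
    GeometryError,
    SelectionError,
)

#: Residue names recognised as water (common force-field dialects).
WATER_RESNAMES = frozenset({"HOH", "WAT", "SOL", "TIP3", "TIP"})
#: Residue names recognised as monovalent sodium cations.
CATION_RESNAMES = frozenset({"NA", "SOD", "NA+"})


# ---------------------------------------------------------------------------
# Selections
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Selection:
    """A deterministic residue-range/atom-name/chain selection.

    Parameters
    ----------
    residue_ranges:
        Inclusive ``(start, stop)`` intervals in author numbering.  Stored
        sorted; overlapping intervals are rejected.
    atom_names:
        Atom names to keep, or ``None`` for all atoms.
    chains:
        Chain identifiers to keep, or ``"all"``.
    """

    residue_ranges: tuple[tuple[int, int], ...]
    atom_names: frozenset[str] | None = None
    chains: tuple[str, ...] | str = "all"

    def __post_init__(self) -> None:
        ranges = tuple(sorted((int(a), int(b)) for a, b in self.residue_ranges))
        for lo, hi in ranges:
            if lo > hi:
                raise SelectionError(f"inverted residue interval {lo}-{hi}")
        for (_, hi), (lo2, _) in zip(ranges, ranges[1:]):
            if lo2 <= hi:
                raise SelectionError("overlapping residue intervals in selection")
        object.__setattr__(self, "residue_ranges", ranges)
        if self.atom_names is not None:
            object.__setattr__(self, "atom_names", frozenset(self.atom_names))

    # -- construction helpers ------------------------------------------------

    @classmethod
    def parse(cls, text: str, atom_names: Iterable[str] | None = ("CA",)) -> "Selection":
        """Parse ``"17-192,196-314"`` (optionally ``"17-192:CA"``) syntax."""
        text = text.strip()
        names = frozenset(atom_names) if atom_names is not None else None
        if ":" in text:
            text, name_part = text.split(":", 1)
            names = frozenset(n.strip().upper() for n in name_part.split("+"))
        ranges = []
        for part in text.split(","):
            part = part.strip()
            m = re.fullmatch(r"(-?\d+)\s*[-:]\s*(-?\d+)", part)
            if m:
                ranges.append((int(m.group(1)), int(m.group(2))))
            elif re.fullmatch(r"-?\d+", part):
                ranges.append((int(part), int(part)))
            else:
                raise SelectionError(f"cannot parse selection fragment {part!r}")
        return cls(tuple(ranges), names)

    @classmethod
    def ca(cls, *ranges: tuple[int, int]) -> "Selection":
        """C-alpha selection over the given inclusive residue intervals."""
        return cls(tuple(ranges), frozenset({"CA"}))

    def residues(self) -> list[int]:
        """All residue numbers covered, ascending."""
        out: list[int] = []
        for lo, hi in self.residue_ranges:
            out.extend(range(lo, hi + 1))
        return out

    def contains(self, residue_number: int) -> bool:
        return any(lo <= residue_number <= hi for lo, hi in self.residue_ranges)

    def subtract(self, intervals: Sequence[tuple[int, int]]) -> "Selection":
        """New selection with the given inclusive intervals removed."""
        keep = sorted(set(self.residues())
                      - {r for lo, hi in intervals for r in range(lo, hi + 1)})
        if not keep:
            raise SelectionError("selection empty after interval subtraction")
        ranges: list[tuple[int, int]] = []
        start = prev = keep[0]
        for r in keep[1:]:
            if r != prev + 1:
                ranges.append((start, prev))
                start = r
            prev = r
        ranges.append((start, prev))
        return Selection(tuple(ranges), self.atom_names, self.chains)


# ---------------------------------------------------------------------------
# Pentamer model
# ---------------------------------------------------------------------------

@dataclass
class PentamerModel:
    """A five-chain atomic model plus labelled heteroatoms (waters, ions).

    ``atoms`` is a biotite :class:`~biotite.structure.AtomArray` carrying the
    annotations; working coordinates live in ``coord`` (float64, Angstrom,
    same atom order) because the AtomArray stores float32 only.  ``chains``
    lists the five protein chain ids in file order.
    """

    atoms: bst.AtomArray
    chains: list[str]
    title: str = ""
    coord: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if len(self.chains) != 5:
            raise AssemblyError(
                f"expected 5 protein chains, got {len(self.chains)}"
            )
        if self.coord is None:
            self.coord = np.array(self.atoms.coord, dtype=np.float64)
        else:
            self.coord = np.asarray(self.coord, dtype=np.float64)
        if self.coord.shape != (self.atoms.array_length(), 3):
            raise FormatError("coord shape must match the atom annotations")
        if not np.all(np.isfinite(self.coord)):
            raise FormatError("non-finite coordinates in model")

    # -- masks ---------------------------------------------------------------

    @property
    def protein_mask(self) -> np.ndarray:
        return (~self.atoms.hetero) & np.isin(self.atoms.chain_id, self.chains)

    @property
    def water_mask(self) -> np.ndarray:
        return np.isin(self.atoms.res_name, list(WATER_RESNAMES))

    @property
    def ion_mask(self) -> np.ndarray:
        return np.isin(self.atoms.res_name, list(CATION_RESNAMES))

    @property
    def n_protein_atoms(self) -> int:
        return int(self.protein_mask.sum())

    def copy(self) -> "PentamerModel":
        return PentamerModel(
            self.atoms.copy(), list(self.chains), self.title, self.coord.copy()
        )

    # -- convenience lookups -------------------------------------------------

    def atom_index(self, chain_id: str, residue_number: int, atom_name: str) -> int:
        """Index of a single named atom; raises SelectionError if absent."""
        a = self.atoms
        hit = np.flatnonzero(
            (a.chain_id == chain_id)
            & (a.res_id == residue_number)
            & (a.atom_name == atom_name)
            & ~a.hetero
        )
        if hit.size != 1:
            raise SelectionError(
                f"atom {chain_id}/{residue_number}/{atom_name}: "
                f"{hit.size} matches (expected 1)"
            )
        return int(hit[0])


def _infer_elements(atom_names: np.ndarray, res_names: np.ndarray) -> np.ndarray:
    """Best-effort element symbols for records missing them."""
    out = np.empty(len(atom_names), dtype="U2")
    for i, (an, rn) in enumerate(zip(atom_names, res_names)):
        if rn in CATION_RESNAMES:
            out[i] = "NA"
        else:
            first = next((c for c in an if c.isalpha()), "C")
            out[i] = first.upper()
    return out


def read_pdb(path: str | Path) -> PentamerModel:
    """Read a PDB file into a :class:`PentamerModel`.

    Altloc duplicates are resolved to the highest-occupancy conformer (ties
    keep the first-listed, conventionally altloc "A").  Waters and cations are
    retained as heteroatoms.  Raises :class:`FormatError` on unparsable input
    or insertion codes, :class:`AssemblyError` if the protein chain count is
    not five.
    """
    path = Path(path)
    try:
        pdb = PDBFile.read(str(path))
        atoms = pdb.get_structure(
            model=1, altloc="occupancy", extra_fields=["occupancy", "b_factor"]
        )
    except AssemblyError:
        raise
    except Exception as exc:  # biotite raises a mix of error types
        raise FormatError(f"cannot parse PDB file {path}: {exc}") from exc
    if atoms.array_length() == 0:
        raise FormatError(f"no ATOM/HETATM records in {path}")
    if np.any(atoms.ins_code != ""):
        raise FormatError(f"insertion codes present in {path}; not supported")
    # some files leave element blank; infer so round-trips stay valid
    blank = atoms.element == ""
    if np.any(blank):
        atoms.element[blank] = _infer_elements(
            atoms.atom_name[blank], atoms.res_name[blank]
        )
    solvent = np.isin(atoms.res_name, list(WATER_RESNAMES | CATION_RESNAMES))
    protein = ~atoms.hetero & ~solvent
    chain_ids = list(dict.fromkeys(atoms.chain_id[protein]))
    if len(chain_ids) != 5:
        raise AssemblyError(
            f"expected 5 protein chains in {path.name}, got {len(chain_ids)}"
        )
    return PentamerModel(atoms, chain_ids, title=path.stem)


def write_pdb(model: PentamerModel, path: str | Path) -> None:
    """Write the model as fixed-column PDB (coordinates to 3 decimals)."""
    atoms = model.atoms.copy()
    atoms.coord = model.coord  # float32 narrowing is below PDB precision
    pdb = PDBFile()
    pdb.set_structure(atoms)
    pdb.write(str(path))


# ---------------------------------------------------------------------------
# Selection resolution
# ---------------------------------------------------------------------------

def resolve_selection(
    model: PentamerModel,
    sel: Selection,
    symmetric: str | None = None,
) -> np.ndarray:
    """Resolve a :class:`Selection` to ordered atom indices.

    Ordering is deterministic: by chain (model chain order), then residue
    number, then atom name — independent of record order in the file.

    Parameters
    ----------
    symmetric:
        ``None`` — no per-chain constraint.  ``"require"`` — raise
        :class:`AsymmetryError` if per-chain (residue, atom) sets differ.
        ``"drop"`` — drop any (residue, atom) position missing from one or
        more chains, with a warning, so per-chain counts stay equal.
    """
    a = model.atoms
    chains = list(model.chains) if sel.chains == "all" else [
        c for c in model.chains if c in sel.chains
    ]
    if not chains:
        raise SelectionError("selection chains do not intersect model chains")
    mask = model.protein_mask & np.isin(a.chain_id, chains)
    res_mask = np.zeros(a.array_length(), dtype=bool)
    for lo, hi in sel.residue_ranges:
        res_mask |= (a.res_id >= lo) & (a.res_id <= hi)
    mask &= res_mask
    if sel.atom_names is not None:
        mask &= np.isin(a.atom_name, list(sel.atom_names))
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        raise SelectionError(
            f"selection {sel.residue_ranges} / {sel.atom_names} resolves to no atoms"
        )

    if symmetric in ("require", "drop"):
        keys_per_chain = {
            c: {(int(r), n) for r, n in
                zip(a.res_id[idx][a.chain_id[idx] == c],
                    a.atom_name[idx][a.chain_id[idx] == c])}
            for c in chains
        }
        common = set.intersection(*keys_per_chain.values())
        union = set.union(*keys_per_chain.values())
        missing = union - common
        if missing:
            if symmetric == "require":
                detail = ", ".join(
                    f"{r}/{n}" for r, n in sorted(missing)[:10]
                )
                raise AsymmetryError(
                    f"selection not symmetric across chains; incomplete "
                    f"positions: {detail}"
                )
            warnings.warn(
                f"dropping {len(missing)} residue/atom positions missing from "
                f"at least one chain", stacklevel=2
            )
            keep = np.array(
                [(int(r), n) in common
                 for r, n in zip(a.res_id[idx], a.atom_name[idx])]
            )
            idx = idx[keep]
            if idx.size == 0:
                raise SelectionError("selection empty after symmetric harmonisation")

    chain_rank = {c: i for i, c in enumerate(chains)}
    order = np.lexsort(
        (a.atom_name[idx], a.res_id[idx],
         np.array([chain_rank[c] for c in a.chain_id[idx]]))
    )
    return idx[order]


def chain_atom_indices(
    model: PentamerModel, sel: Selection, symmetric: str = "drop"
) -> dict[str, np.ndarray]:
    """Per-chain ordered index arrays for a symmetric selection."""
    idx = resolve_selection(model, sel, symmetric=symmetric)
    cid = model.atoms.chain_id[idx]
    return {c: idx[cid == c] for c in model.chains if np.any(cid == c)}


# ---------------------------------------------------------------------------
# Subunit azimuthal order
# ---------------------------------------------------------------------------

def subunit_order(model: PentamerModel, axis) -> list[str]:
    """Chains ordered counterclockwise about the pore axis, viewed from the
    extracellular (+direction) side.

    The complementary neighbour of chain ``order[i]`` is ``order[(i+1) % 5]``.
    The first chain is the one of smallest azimuth in an axis-fixed frame, so
    the result is stable under record permutation; rigid rotation of the model
    changes the result only by a cyclic shift.
    """
    from .pore_geometry import PoreAxis  # local import to avoid cycle

    if not isinstance(axis, PoreAxis):
        raise TypeError("axis must be a PoreAxis")
    a = model.atoms
    u, v = axis.perpendicular_basis()
    azimuths = {}
    for c in model.chains:
        m = model.protein_mask & (a.chain_id == c) & (a.atom_name == "CA")
        if not np.any(m):
            raise SelectionError(f"chain {c} has no CA atoms")
        centroid = model.coord[m].mean(axis=0) - axis.point
        x, y = centroid @ u, centroid @ v
        if np.hypot(x, y) < 1e-9:
            raise GeometryError(f"chain {c} centroid lies on the pore axis")
        az = np.arctan2(y, x)
        if az < -1e-9:  # wrap to [0, 2*pi) with tolerance so azimuth ~0 stays 0
            az += 2 * np.pi
        azimuths[c] = az
    ordered = sorted(model.chains, key=lambda c: azimuths[c])
    angles = np.array([azimuths[c] for c in ordered])
    gaps = np.diff(np.concatenate([angles, [angles[0] + 2 * np.pi]]))
    if np.any(gaps < 1e-6):
        pair = ordered[int(np.argmin(gaps))]
        raise GeometryError(
            f"degenerate subunit geometry: indistinguishable azimuths near chain {pair}"
        )
    return ordered


# ---------------------------------------------------------------------------
# Trajectory frame sets
# ---------------------------------------------------------------------------

@dataclass
class TrajectoryFrameSet:
    """A topology-bound sequence of coordinate frames.

    ``coords`` has shape ``(n_frames, n_atoms, 3)`` in Angstrom, atom order
    identical to ``model.atoms``; ``times`` in nanoseconds.
    """

    model: PentamerModel
    coords: np.ndarray
    times: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise FormatError("coords must have shape (n_frames, n_atoms, 3)")
        if self.coords.shape[1] != self.model.atoms.array_length():
            raise FormatError(
                f"frame atom count {self.coords.shape[1]} != topology atom "
                f"count {self.model.atoms.array_length()}"
            )
        if self.times is None:
            self.times = np.arange(self.n_frames, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.times.shape != (self.n_frames,):
            raise FormatError("times length must equal frame count")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    def frame_model(self, i: int) -> PentamerModel:
        """A PentamerModel whose coordinates are frame ``i`` (copied)."""
        m = self.model.copy()
        m.coord = np.array(self.coords[i], dtype=np.float64)
        return m

    def window(self, last_ns: float | None) -> "TrajectoryFrameSet":
        """Restrict to the final ``last_ns`` nanoseconds (None = all)."""
        if last_ns is None or self.n_frames == 0:
            return self
        keep = self.times >= self.times[-1] - last_ns + 1e-9
        return TrajectoryFrameSet(self.model, self.coords[keep], self.times[keep])


def read_trajectory(
    topology_path: str | Path,
    trajectory_path: str | Path,
    frame_dt_ns: float | None = None,
    t0_ns: float = 0.0,
) -> TrajectoryFrameSet:
    """Load DCD/XTC/TRR frames against a PDB topology (via mdtraj).

    DCD headers do not carry absolute times portably, so for DCD input the
    frame times are ``t0_ns + i * frame_dt_ns`` (default spacing 1 ns);
    for other formats the file's own times are used unless ``frame_dt_ns``
    overrides them.
    """
    import mdtraj as md

    model = read_pdb(topology_path)
    try:
        traj = md.load(str(trajectory_path), top=str(topology_path))
    except Exception as exc:
        raise FormatError(
            f"cannot read trajectory {trajectory_path}: {exc}"
        ) from exc
    if traj.n_atoms != model.atoms.array_length():
        raise FormatError(
            f"trajectory atom count {traj.n_atoms} != topology "
            f"{model.atoms.array_length()}"
        )
    coords = np.asarray(traj.xyz, dtype=np.float64) * 10.0  # nm -> A
    is_dcd = str(trajectory_path).lower().endswith(".dcd")
    if frame_dt_ns is not None or is_dcd:
        dt = 1.0 if frame_dt_ns is None else frame_dt_ns
        times = t0_ns + np.arange(traj.n_frames) * dt
    else:
        times = np.asarray(traj.time, dtype=float) / 1000.0  # ps -> ns
    return TrajectoryFrameSet(model, coords, times)


def write_trajectory(
    frames: TrajectoryFrameSet, topology_path: str | Path, trajectory_path: str | Path
) -> None:
    """Write the topology as PDB and the frames as DCD (via mdtraj)."""
    import mdtraj as md

    write_pdb(frames.model, topology_path)
    top = md.load(str(topology_path)).topology
    traj = md.Trajectory(
        xyz=frames.coords / 10.0,
        topology=top,
        time=frames.times * 1000.0,
    )
    traj.save(str(trajectory_path))
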