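"""Synthetic C5 pentamer models and mock trajectories with known ground truth.

The generator emulates the statistical structure of the observables the
analyses measure — per-residue pore ring radii with a 2.9 A constriction at
the 9' gate, an extracellular block with controllable spread and twist, a
two-state (formed/broken) salt-bridge process with stated switching
probabilities, diffusing monovalent cations, and pore/bulk waters — so every
stage of the pipeline is testable without downloads.  The protein stand-ins
are C-alpha skeletons plus the named marker atoms the analyses touch
(E35 OE1/OE2, T158 OG1, I233 CB, A237 CB, E243 OE1/OE2, K248 NZ); they are
not chemically valid structures.

Construction guarantees, for noiseless specs:

* every chain's C-alpha atoms sit in a single axial half-plane, 72 degrees
  apart, so ring centroids lie exactly on the z axis and subunit centres of
  mass have exact azimuths;
* extracellular C-alpha atoms all sit at radius ``ecd_spread_target``, so the
  spread descriptor recovers the target exactly;
* the T158 stand-in of each complementary subunit is placed a prescribed
  distance from the principal E35 stand-in by a symmetric construction whose
  azimuthal offsets cancel pairwise (a compensating offset on residue 159),
  preserving both spread and subunit-COM azimuths;
* the K248 NZ stand-in toggles between a contact pose at an exact distance
  from the E243 carboxylate and a released pose, driven by a seeded
  two-state Markov chain per subunit.

All randomness flows from one explicit seeded generator.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import biotite.structure as bst

from .errors import ConfigError
from .structure_io import PentamerModel, TrajectoryFrameSet, write_trajectory

FIRST_RESIDUE = 10
ECD_LAST_RESIDUE = 192          # residues <= this form the rotatable ECD block
LINING_RANGE = (222, 247)
TMD_DEFAULT_RADIUS = 12.0       # A, C-alpha radius of non-pore-lining TMD residues
GATE_RESIDUE = 233
UPPER_GATE_RESIDUE = 237
Z_PER_RESIDUE = 0.8             # A of axial drop per residue number
Z_ORIGIN_RESIDUE = 230          # residue whose ring sits at z = 0

MARKER_RESNAMES = {35: "GLU", 158: "THR", 233: "ILE", 237: "ALA",
                   243: "GLU", 248: "LYS"}

_CHAINS = ("A", "B", "C", "D", "E")


def default_ring_radii() -> dict[int, float]:
    """A GLIC-like V-shaped C-alpha ring profile with its minimum, 2.9 A,
    at the 9' gate residue 233."""
    return {i: 2.9 + 0.35 * abs(i - GATE_RESIDUE)
            for i in range(LINING_RANGE[0], LINING_RANGE[1] + 1)}


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic pentamer and trajectory.

    Distances in Angstrom, times in nanoseconds, angles in degrees;
    switching parameters are per-frame probabilities.
    """

    n_residues_per_chain: int = 305           # residues 10..314
    ring_radii: dict[int, float] = field(default_factory=default_ring_radii)
    ecd_spread_target: float = 25.0
    twist_deg: float = 0.0
    breathing_amplitude: float = 0.0
    twist_drift: float = 0.0                  # degrees per frame
    spread_series: np.ndarray | None = None   # explicit per-frame override
    twist_series: np.ndarray | None = None
    contact_k_on: float = 0.0                 # broken -> formed
    contact_k_off: float = 0.0                # formed -> broken
    contact_initial: str = "formed"
    contact_formed_distance: float = 2.8
    contact_broken_distance: float = 8.0
    iface_ca_distance: float = 9.0            # E35 CA to complementary T158 CA
    iface_o_distance: float = 3.2             # E35 OE to complementary T158 OG1
    n_ions: int = 0
    n_waters_in_pore: int = 0
    n_waters_bulk: int = 0
    noise_sigma: float = 0.0
    n_frames: int = 1
    frame_dt_ns: float = 1.0
    seed: int | None = None

    def __post_init__(self) -> None:
        last = FIRST_RESIDUE + self.n_residues_per_chain - 1
        if last < 270:
            raise ConfigError(
                "n_residues_per_chain too small: model must reach residue 270"
            )
        for k, v in self.ring_radii.items():
            if not (LINING_RANGE[0] <= k <= LINING_RANGE[1]):
                raise ConfigError(f"ring_radii residue {k} outside {LINING_RANGE}")
            if v <= 0:
                raise ConfigError(f"ring radius for residue {k} must be positive")
        for name in ("contact_k_on", "contact_k_off"):
            p = getattr(self, name)
            if not (0.0 <= p <= 1.0):
                raise ConfigError(f"{name} must be a probability, got {p}")
        if self.contact_initial not in ("formed", "broken"):
            raise ConfigError("contact_initial must be 'formed' or 'broken'")
        if self.n_frames < 1:
            raise ConfigError("n_frames must be >= 1")
        if self.ecd_spread_target <= 0:
            raise ConfigError("ecd_spread_target must be positive")
        if self.iface_ca_distance >= 2 * self.ecd_spread_target:
            raise ConfigError("iface_ca_distance infeasible at this spread")
        if self._stochastic and self.seed is None:
            raise ConfigError(
                "seed is mandatory when any stochastic field is active"
            )

    @property
    def _stochastic(self) -> bool:
        return (
            self.noise_sigma > 0
            or self.n_ions > 0
            or self.n_waters_in_pore > 0
            or self.n_waters_bulk > 0
            or self.contact_k_on > 0
            or self.contact_k_off > 0
        )

    @property
    def last_residue(self) -> int:
        return FIRST_RESIDUE + self.n_residues_per_chain - 1

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(0 if self.seed is None else self.seed)


@dataclass
class GroundTruth:
    """Exact per-frame generating values, for recovery tests."""

    times: np.ndarray
    spread: np.ndarray
    twist: np.ndarray
    contact_state: np.ndarray   # (n_frames, 5) bool, True = formed
    water_count: np.ndarray     # in-pore waters per frame

    def to_json(self) -> str:
        return json.dumps(
            {
                "times": self.times.tolist(),
                "spread": self.spread.tolist(),
                "twist": self.twist.tolist(),
                "contact_state": self.contact_state.astype(int).tolist(),
                "water_count": self.water_count.tolist(),
            },
            indent=1,
        )


def _z(res: int) -> float:
    return (Z_ORIGIN_RESIDUE - res) * Z_PER_RESIDUE


def _rotz(deg: float) -> np.ndarray:
    t = np.radians(deg)
    c, s = np.cos(t), np.sin(t)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _cyl(radius: float, azimuth_deg: float, z: float) -> np.ndarray:
    t = np.radians(azimuth_deg)
    return np.array([radius * np.cos(t), radius * np.sin(t), z])


class _Builder:
    """Shared geometry between the static model and trajectory frames."""

    def __init__(self, spec: SyntheticSpec):
        self.spec = spec
        rows = []  # (chain, res_id, res_name, atom_name, element, xyz)
        s = spec
        r_ecd = s.ecd_spread_target

        # interface construction: T158 CA of chain j sits near the azimuth of
        # chain j-1 (loop F reaches the principal subunit), at an exact
        # distance from that subunit's E35 CA; residue 159 carries the
        # compensating azimuthal offset so subunit-COM azimuths stay exact.
        dz = 0.6 * s.iface_ca_distance
        chord = 0.8 * s.iface_ca_distance
        eps = np.degrees(2 * np.arcsin(chord / (2 * r_ecd)))
        gamma_158 = -72.0 + eps
        gamma_159 = +72.0 - eps
        z35 = _z(35)
        z158 = z35 - dz

        for ci, chain in enumerate(_CHAINS):
            az = 72.0 * ci
            for res in range(FIRST_RESIDUE, s.last_residue + 1):
                res_name = MARKER_RESNAMES.get(res, "ALA")
                if res == 158:
                    xyz = _cyl(r_ecd, az + gamma_158, z158)
                elif res == 159:
                    xyz = _cyl(r_ecd, az + gamma_159, _z(res))
                elif res <= ECD_LAST_RESIDUE:
                    xyz = _cyl(r_ecd, az, _z(res))
                else:
                    radius = s.ring_radii.get(res, TMD_DEFAULT_RADIUS)
                    xyz = _cyl(radius, az, _z(res))
                rows.append((chain, res, res_name, "CA", "C", xyz))

                if res == 35:
                    # OE atoms placed off the complementary OG1 (chain ci+1),
                    # radially inward, at the exact prescribed distance
                    og_az = az + 72.0 + gamma_158  # = az + eps
                    og = _cyl(r_ecd - 1.0, og_az, z158 - 0.8)
                    w = -np.array([np.cos(np.radians(og_az)),
                                   np.sin(np.radians(og_az)), 0.0])
                    rows.append((chain, res, "GLU", "OE1", "O",
                                 og + s.iface_o_distance * w))
                    rows.append((chain, res, "GLU", "OE2", "O",
                                 og + (s.iface_o_distance + 1.2) * w))
                elif res == 158:
                    rows.append((chain, res, "THR", "OG1", "O",
                                 _cyl(r_ecd - 1.0, az + gamma_158, z158 - 0.8)))
                elif res == 233:
                    rows.append((chain, res, "ILE", "CB", "C",
                                 _cyl(s.ring_radii.get(res, 2.9), az + 4.0,
                                      _z(res) - 0.4)))
                elif res == 237:
                    rows.append((chain, res, "ALA", "CB", "C",
                                 _cyl(s.ring_radii.get(res, 4.3), az + 4.0,
                                      _z(res) - 0.4)))
                elif res == 243:
                    r243 = s.ring_radii.get(res, 6.4)
                    rows.append((chain, res, "GLU", "OE1", "O",
                                 _cyl(r243 + 1.5, az, _z(res) - 0.3)))
                    rows.append((chain, res, "GLU", "OE2", "O",
                                 _cyl(r243 + 0.2, az, _z(res) - 0.3)))
                elif res == 248:
                    # placeholder; set from the contact pose below
                    rows.append((chain, res, "LYS", "NZ", "N", np.zeros(3)))

        self.protein_rows = rows
        self.n_protein = len(rows)
        self.nz_index = {
            chain: next(
                i for i, r in enumerate(rows)
                if r[0] == chain and r[1] == 248 and r[3] == "NZ"
            )
            for chain in _CHAINS
        }
        r243 = s.ring_radii.get(243, 6.4)
        self.nz_pose = {}
        for ci, chain in enumerate(_CHAINS):
            az = 72.0 * ci
            oe1 = _cyl(r243 + 1.5, az, _z(243) - 0.3)
            out = np.array([np.cos(np.radians(az)), np.sin(np.radians(az)), 0.0])
            self.nz_pose[chain] = {
                True: oe1 + s.contact_formed_distance * out,
                False: oe1 + s.contact_broken_distance * out,
            }

        self.ecd_mask = np.array(
            [r[1] <= ECD_LAST_RESIDUE for r in rows], dtype=bool
        )
        self.base = np.array([r[5] for r in rows], dtype=float)

    # -- solvent -------------------------------------------------------------

    def water_positions(self, rng: np.random.Generator) -> np.ndarray:
        s = self.spec
        zlo, zhi = sorted((_z(GATE_RESIDUE), _z(UPPER_GATE_RESIDUE)))
        margin = 0.1 * (zhi - zlo)
        waters = []
        for _ in range(s.n_waters_in_pore):
            r = rng.uniform(0.0, 2.0)
            t = rng.uniform(0.0, 2 * np.pi)
            z = rng.uniform(zlo + margin, zhi - margin)
            waters.append([r * np.cos(t), r * np.sin(t), z])
        for _ in range(s.n_waters_bulk):
            r = rng.uniform(30.0, 50.0)
            t = rng.uniform(0.0, 2 * np.pi)
            z = rng.uniform(-40.0, 40.0)
            waters.append([r * np.cos(t), r * np.sin(t), z])
        return np.asarray(waters, dtype=float).reshape(-1, 3)

    def ion_positions(self, rng: np.random.Generator) -> np.ndarray:
        s = self.spec
        ions = []
        for _ in range(s.n_ions):
            r = rng.uniform(28.0, 45.0)
            t = rng.uniform(0.0, 2 * np.pi)
            z = rng.uniform(-30.0, 120.0)
            ions.append([r * np.cos(t), r * np.sin(t), z])
        return np.asarray(ions, dtype=float).reshape(-1, 3)

    # -- frame assembly ------------------------------------------------------

    def protein_frame(
        self,
        spread: float,
        twist: float,
        states: dict[str, bool],
        rng: np.random.Generator | None,
    ) -> np.ndarray:
        s = self.spec
        xyz = self.base.copy()
        scale = spread / s.ecd_spread_target
        ecd = xyz[self.ecd_mask]
        ecd[:, :2] *= scale
        xyz[self.ecd_mask] = ecd @ _rotz(twist).T
        for chain in _CHAINS:
            xyz[self.nz_index[chain]] = self.nz_pose[chain][states[chain]]
        if s.noise_sigma > 0 and rng is not None:
            xyz += rng.normal(0.0, s.noise_sigma, size=xyz.shape)
        return xyz


def _assemble_model(
    builder: _Builder, protein_xyz: np.ndarray,
    waters: np.ndarray, ions: np.ndarray, title: str,
) -> PentamerModel:
    rows = builder.protein_rows
    n = len(rows) + len(waters) + len(ions)
    atoms = bst.AtomArray(n)
    atoms.add_annotation("occupancy", dtype=float)
    atoms.add_annotation("b_factor", dtype=float)
    coords = np.empty((n, 3))
    for i, (chain, res, res_name, atom_name, element, _) in enumerate(rows):
        atoms.chain_id[i] = chain
        atoms.res_id[i] = res
        atoms.res_name[i] = res_name
        atoms.atom_name[i] = atom_name
        atoms.element[i] = element
        atoms.hetero[i] = False
        coords[i] = protein_xyz[i]
    k = len(rows)
    for j, w in enumerate(waters):
        i = k + j
        atoms.chain_id[i] = "W"
        atoms.res_id[i] = j + 1
        atoms.res_name[i] = "HOH"
        atoms.atom_name[i] = "O"
        atoms.element[i] = "O"
        atoms.hetero[i] = True
        coords[i] = w
    k += len(waters)
    for j, p in enumerate(ions):
        i = k + j
        atoms.chain_id[i] = "I"
        atoms.res_id[i] = j + 1
        atoms.res_name[i] = "NA"
        atoms.atom_name[i] = "NA"
        atoms.element[i] = "NA"
        atoms.hetero[i] = True
        coords[i] = p
    atoms.coord = coords
    atoms.occupancy[:] = 1.0
    atoms.b_factor[:] = 0.0
    atoms.ins_code[:] = ""
    return PentamerModel(atoms, list(_CHAINS), title=title, coord=coords)


def generate_pentamer(spec: SyntheticSpec) -> PentamerModel:
    """An exact C5 model about the z axis (chains A-E at azimuths 0, 72, ...),
    with the spec's spread, twist, ring radii, and initial contact pose."""
    builder = _Builder(spec)
    rng = spec.rng()
    states = {c: spec.contact_initial == "formed" for c in _CHAINS}
    protein = builder.protein_frame(
        spec.ecd_spread_target, spec.twist_deg, states,
        rng if spec.noise_sigma > 0 else None,
    )
    waters = builder.water_positions(rng)
    ions = builder.ion_positions(rng)
    return _assemble_model(builder, protein, waters, ions, "synthetic-c5")


def _descriptor_schedules(spec: SyntheticSpec) -> tuple[np.ndarray, np.ndarray]:
    t = np.arange(spec.n_frames)
    if spec.spread_series is not None:
        spread = np.asarray(spec.spread_series, dtype=float)
        if spread.shape != (spec.n_frames,):
            raise ConfigError("spread_series length must equal n_frames")
    else:
        spread = spec.ecd_spread_target + spec.breathing_amplitude * np.sin(
            2 * np.pi * t / max(spec.n_frames, 2)
        )
    if spec.twist_series is not None:
        twist = np.asarray(spec.twist_series, dtype=float)
        if twist.shape != (spec.n_frames,):
            raise ConfigError("twist_series length must equal n_frames")
    else:
        twist = spec.twist_deg + spec.twist_drift * t
    return spread, twist


def generate_trajectory(
    spec: SyntheticSpec,
) -> tuple[TrajectoryFrameSet, GroundTruth]:
    """Frames with breathing, twist drift, the two-state contact process,
    ion random walks, and jittering waters; plus the exact generating series."""
    builder = _Builder(spec)
    rng = spec.rng()
    spread, twist = _descriptor_schedules(spec)

    # per-subunit two-state Markov chains
    states = np.empty((spec.n_frames, 5), dtype=bool)
    current = np.full(5, spec.contact_initial == "formed")
    for f in range(spec.n_frames):
        if f > 0:
            u = rng.random(5)
            current = np.where(
                current, u >= spec.contact_k_off, u < spec.contact_k_on
            )
        states[f] = current

    waters0 = builder.water_positions(rng)
    ions = builder.ion_positions(rng)
    n_atoms = builder.n_protein + len(waters0) + len(ions)
    coords = np.empty((spec.n_frames, n_atoms, 3), dtype=np.float64)
    k1, k2 = builder.n_protein, builder.n_protein + len(waters0)
    for f in range(spec.n_frames):
        state_map = dict(zip(_CHAINS, states[f]))
        coords[f, :k1] = builder.protein_frame(
            spread[f], twist[f], state_map,
            rng if spec.noise_sigma > 0 else None,
        )
        if len(waters0):
            coords[f, k1:k2] = waters0 + rng.uniform(
                -0.05, 0.05, size=waters0.shape
            )
        if len(ions):
            ions = ions + rng.normal(0.0, 1.0, size=ions.shape)
            coords[f, k2:] = ions

    model = _assemble_model(
        builder, np.asarray(coords[0, :k1], dtype=float),
        np.asarray(coords[0, k1:k2], dtype=float),
        np.asarray(coords[0, k2:], dtype=float), "synthetic-c5-traj",
    )
    times = np.arange(spec.n_frames) * spec.frame_dt_ns
    truth = GroundTruth(
        times=times,
        spread=spread,
        twist=twist,
        contact_state=states,
        water_count=np.full(spec.n_frames, spec.n_waters_in_pore, dtype=int),
    )
    return TrajectoryFrameSet(model, coords, times), truth


def write_fixture(spec: SyntheticSpec, directory: str | Path) -> dict[str, Path]:
    """Write model.pdb, traj.dcd, ground_truth.json, and spec.json.

    Re-reading the PDB through :func:`structure_io.read_pdb` reproduces the
    in-memory model at PDB fixed-width precision; equal seeds give
    byte-identical trajectory payloads.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    traj, truth = generate_trajectory(spec)
    paths = {
        "topology": directory / "model.pdb",
        "trajectory": directory / "traj.dcd",
        "ground_truth": directory / "ground_truth.json",
        "spec": directory / "spec.json",
    }
    try:
        write_trajectory(traj, paths["topology"], paths["trajectory"])
        paths["ground_truth"].write_text(truth.to_json())
        spec_dict = asdict(spec)
        for key in ("spread_series", "twist_series"):
            if spec_dict[key] is not None:
                spec_dict[key] = np.asarray(spec_dict[key]).tolist()
        paths["spec"].write_text(json.dumps(spec_dict, indent=1))
    except OSError as exc:
        raise OSError(f"cannot write fixture under {directory}: {exc}") from exc
    return paths
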