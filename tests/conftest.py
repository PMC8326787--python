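"""Shared fixtures: synthetic pentamers and tiny handwritten PDB texts."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

import pentagate as pg

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_spec() -> pg.SyntheticSpec:
    return pg.SyntheticSpec()


@pytest.fixture(scope="session")
def _ideal_model_cached(default_spec) -> pg.PentamerModel:
    return pg.generate_pentamer(default_spec)


@pytest.fixture()
def ideal_model(_ideal_model_cached) -> pg.PentamerModel:
    """A noiseless C5 pentamer about the z axis (fresh copy per test)."""
    return _ideal_model_cached.copy()


@pytest.fixture()
def ideal_axis(ideal_model) -> pg.PoreAxis:
    return pg.estimate_pore_axis(ideal_model)


def random_rigid_motion(rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """A uniform-ish random proper rotation and a translation."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    rot = np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])
    return rot, rng.uniform(-20, 20, size=3)


def apply_rigid(model: pg.PentamerModel, rot: np.ndarray, trans: np.ndarray):
    moved = model.copy()
    moved.coord = model.coord @ rot.T + trans
    return moved


def make_pdb_text(
    n_chains: int = 5,
    n_atoms_per_chain: int = 100,
    altloc_atom: tuple[float, float] | None = None,
    insertion_code: bool = False,
) -> str:
    """Minimal ATOM-record PDB text: one CA per residue, helical coords.

    ``altloc_atom`` = (occ_A, occ_B) duplicates the first atom of chain A in
    two alternate locations.
    """
    lines = []
    serial = 1

    def atom_line(serial, name, altloc, resname, chain, resseq, x, y, z, occ,
                  icode=" "):
        return (
            f"ATOM  {serial:5d}  {name:<3s}{altloc}{resname:>3s} {chain}"
            f"{resseq:4d}{icode}   {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{0.0:6.2f}"
            f"          {name[0]:>2s}"
        )

    for ci in range(n_chains):
        chain = "ABCDEFG"[ci]
        az = np.radians(72.0 * ci)
        for ri in range(n_atoms_per_chain):
            res = ri + 10
            x = 20.0 * np.cos(az) + 0.1 * ri
            y = 20.0 * np.sin(az)
            z = 1.3 * ri
            if ci == 0 and ri == 0 and altloc_atom is not None:
                occ_a, occ_b = altloc_atom
                lines.append(atom_line(serial, "CA", "A", "ALA", chain, res,
                                       x, y, z, occ_a))
                serial += 1
                lines.append(atom_line(serial, "CA", "B", "ALA", chain, res,
                                       x + 0.5, y, z, occ_b))
                serial += 1
                continue
            icode = "A" if (insertion_code and ci == 0 and ri == 1) else " "
            lines.append(atom_line(serial, "CA", " ", "ALA", chain, res,
                                   x, y, z, 1.0, icode))
            serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"
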