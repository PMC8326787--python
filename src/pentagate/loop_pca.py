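"""Principal-component landscapes of the M2-M3 loop.

Observations are C-alpha coordinates of the loop (default E243-P250, eight
residues, 24 coordinates) with each subunit treated separately.  Because a
naive whole-pentamer superposition would leave subunits 72 degrees apart and
the leading component would simply measure that rotation, every subunit is
first brought into a common subunit frame by superposing its flanking core
C-alpha atoms (default M2 222-242 plus M3 251-270) onto a designated
reference subunit.  PCA is then an eigendecomposition of the row covariance
(rows centred, no column scaling — all columns share Angstrom units).

Component signs are fixed so each component's largest-magnitude loading is
positive, making results deterministic across eigensolvers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import InsufficientDataError, PairingError, SelectionError
from .pore_geometry import estimate_pore_axis
from .structure_io import (
    PentamerModel,
    Selection,
    TrajectoryFrameSet,
    subunit_order,
)
from .superposition import kabsch_fit

DEFAULT_LOOP_RANGE = (243, 250)
DEFAULT_CORE_RANGES = ((222, 242), (251, 270))


@dataclass
class LoopObservationMatrix:
    """Rows of flattened loop coordinates in the common subunit frame.

    ``matrix`` has shape (n_observations, 3L); ``labels`` carries one
    (model_name, chain_id) pair per row; ``provenance`` records the loop and
    core ranges and the reference subunit used for superposition.
    """

    matrix: np.ndarray
    labels: list[tuple[str, str]]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise ValueError("observation matrix must be 2-D")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("non-finite values in observation matrix")
        if len(self.labels) != self.matrix.shape[0]:
            raise ValueError("one label per row required")


@dataclass(frozen=True)
class PCModel:
    """Mean, orthonormal components (rows), and explained-variance fractions."""

    mean: np.ndarray
    components: np.ndarray
    explained_fraction: np.ndarray

    def __post_init__(self) -> None:
        gram = self.components @ self.components.T
        if not np.allclose(gram, np.eye(len(self.components)), atol=1e-8):
            raise ValueError("components must be orthonormal")
        ef = np.asarray(self.explained_fraction)
        if np.any(np.diff(ef) > 1e-12) or np.any(ef < -1e-12) or np.any(ef > 1 + 1e-12):
            raise ValueError("explained fractions must be non-increasing in [0, 1]")


def _loop_atoms(
    model: PentamerModel, chain: str, sel: Selection
) -> np.ndarray | None:
    """Ordered C-alpha indices of `sel` on one chain, or None if incomplete."""
    a = model.atoms
    idx = []
    for res in sel.residues():
        hit = np.flatnonzero(
            model.protein_mask
            & (a.chain_id == chain)
            & (a.res_id == res)
            & (a.atom_name == "CA")
        )
        if hit.size != 1:
            return None
        idx.append(int(hit[0]))
    return np.asarray(idx, dtype=int)


def extract_loop_observations(
    models: list[PentamerModel],
    loop: tuple[int, int] = DEFAULT_LOOP_RANGE,
    core: tuple[tuple[int, int], ...] = DEFAULT_CORE_RANGES,
    model_names: list[str] | None = None,
) -> LoopObservationMatrix:
    """Per-subunit loop coordinates in a common subunit frame.

    The reference subunit is the azimuthally first chain of the first model.
    Each subunit's flanking-core C-alpha set is superposed onto the reference
    core; the resulting transform is applied to the loop C-alpha atoms, whose
    coordinates are concatenated into one row.  Subunits missing a loop
    C-alpha are skipped with a warning.
    """
    if not models:
        raise InsufficientDataError("no models supplied")
    loop_sel = Selection.ca(loop)
    core_sel = Selection.ca(*core)
    names = model_names or [m.title or f"model{i}" for i, m in enumerate(models)]

    ref_model = models[0]
    ref_chain = subunit_order(ref_model, estimate_pore_axis(ref_model))[0]
    ref_core_idx = _loop_atoms(ref_model, ref_chain, core_sel)
    if ref_core_idx is None:
        raise SelectionError(
            f"reference subunit {ref_chain} incomplete over core ranges {core}"
        )
    ref_core = ref_model.coord[ref_core_idx]

    rows, labels = [], []
    for name, model in zip(names, models):
        order = subunit_order(model, estimate_pore_axis(model))
        for chain in order:
            core_idx = _loop_atoms(model, chain, core_sel)
            loop_idx = _loop_atoms(model, chain, loop_sel)
            if core_idx is None or loop_idx is None:
                warnings.warn(
                    f"{name}/{chain}: incomplete loop or core C-alpha; row skipped",
                    stacklevel=2,
                )
                continue
            if core_idx.size != ref_core.shape[0]:
                raise PairingError(
                    f"{name}/{chain}: core atom count {core_idx.size} != "
                    f"reference {ref_core.shape[0]}"
                )
            fit = kabsch_fit(model.coord[core_idx], ref_core)
            rows.append(fit.apply(model.coord[loop_idx]).ravel())
            labels.append((name, chain))
    if len(rows) < 3:
        raise InsufficientDataError(
            f"only {len(rows)} usable subunit observations (need >= 3)"
        )
    return LoopObservationMatrix(
        np.vstack(rows),
        labels,
        provenance={
            "loop": loop,
            "core": core,
            "reference": (names[0], ref_chain),
        },
    )


def fit_pca(obs: LoopObservationMatrix | np.ndarray) -> PCModel:
    """Eigendecomposition of the centred row covariance (divisor n - 1).

    Explained fractions are eigenvalues over their sum.  All components with
    nonzero variance are retained (at most min(n - 1, 3L)).
    """
    x = obs.matrix if isinstance(obs, LoopObservationMatrix) else np.asarray(obs, float)
    n, p = x.shape
    if n < 3 or p < 2:
        raise InsufficientDataError(f"need >= 3 rows and >= 2 columns, got {x.shape}")
    mean = x.mean(axis=0)
    xc = x - mean
    # SVD of the centred matrix == eigendecomposition of the covariance
    _, svals, vt = np.linalg.svd(xc, full_matrices=False)
    eigvals = svals**2 / (n - 1)
    total = eigvals.sum()
    if total < 1e-12:
        raise InsufficientDataError("degenerate observations: zero total variance")
    keep = eigvals > max(1e-12 * total, 1e-300)
    comps = vt[keep]
    eigvals = eigvals[keep]
    # deterministic sign: largest-|loading| coordinate positive
    for i in range(comps.shape[0]):
        j = int(np.argmax(np.abs(comps[i])))
        if comps[i, j] < 0:
            comps[i] = -comps[i]
    return PCModel(mean, comps, eigvals / total)


def project(
    observations: LoopObservationMatrix | np.ndarray,
    model: PCModel,
    n_components: int = 2,
) -> np.ndarray:
    """Project rows onto the leading components; the training mean maps to 0."""
    x = (
        observations.matrix
        if isinstance(observations, LoopObservationMatrix)
        else np.atleast_2d(np.asarray(observations, dtype=float))
    )
    if x.shape[1] != model.mean.shape[0]:
        raise PairingError(
            f"observation dimension {x.shape[1]} != PC model dimension "
            f"{model.mean.shape[0]}"
        )
    k = min(n_components, model.components.shape[0])
    return (x - model.mean) @ model.components[:k].T


def project_trajectory(
    traj: TrajectoryFrameSet,
    model: PCModel,
    loop: tuple[int, int] = DEFAULT_LOOP_RANGE,
    core: tuple[tuple[int, int], ...] = DEFAULT_CORE_RANGES,
    reference: PentamerModel | None = None,
    n_components: int = 2,
) -> tuple[np.ndarray, list[tuple[int, str]]]:
    """Per-frame, per-subunit projections of trajectory loop conformations.

    The common subunit frame is defined by ``reference`` (default: the
    trajectory topology) exactly as in :func:`extract_loop_observations`.
    Returns (projections of shape (n_frames * 5, k), labels of
    (frame_index, chain_id)).
    """
    ref = reference if reference is not None else traj.model
    loop_sel = Selection.ca(loop)
    core_sel = Selection.ca(*core)
    ref_chain = subunit_order(ref, estimate_pore_axis(ref))[0]
    ref_core_idx = _loop_atoms(ref, ref_chain, core_sel)
    if ref_core_idx is None:
        raise SelectionError("reference subunit incomplete over core ranges")
    ref_core = ref.coord[ref_core_idx]

    top = traj.model
    per_chain = []
    for chain in top.chains:
        core_idx = _loop_atoms(top, chain, core_sel)
        loop_idx = _loop_atoms(top, chain, loop_sel)
        if core_idx is None or loop_idx is None:
            raise SelectionError(f"chain {chain}: incomplete loop/core C-alpha")
        per_chain.append((chain, core_idx, loop_idx))

    rows, labels = [], []
    for fi in range(traj.n_frames):
        xyz = np.asarray(traj.coords[fi], dtype=float)
        for chain, core_idx, loop_idx in per_chain:
            fit = kabsch_fit(xyz[core_idx], ref_core)
            rows.append(fit.apply(xyz[loop_idx]).ravel())
            labels.append((fi, chain))
    return project(np.vstack(rows), model, n_components), labels


def kde2d(
    points: np.ndarray,
    bandwidth: str | tuple[float, float] = "scott",
    grid_size: int = 128,
    padding: float = 3.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gaussian kernel density on a regular grid.

    Bandwidths follow Scott's rule per dimension (``sigma_i * n^(-1/6)``) or
    may be given explicitly.  The grid spans the data plus ``padding``
    bandwidths on each side; the returned density integrates to ~1 over the
    grid (trapezoidal).  Returns (x_grid, y_grid, density[ny, nx]).
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.shape[0] < 2 or pts.shape[1] != 2:
        raise InsufficientDataError("kde2d needs >= 2 two-dimensional points")
    n = pts.shape[0]
    if bandwidth == "scott":
        sigma = pts.std(axis=0, ddof=1)
        if np.any(sigma <= 0):
            raise InsufficientDataError(
                "zero variance in a dimension; supply explicit bandwidths"
            )
        h = sigma * n ** (-1.0 / 6.0)
    else:
        h = np.asarray(bandwidth, dtype=float)
        if h.shape != (2,) or np.any(h <= 0):
            raise ValueError("bandwidth must be 'scott' or two positive floats")
    x = np.linspace(pts[:, 0].min() - padding * h[0],
                    pts[:, 0].max() + padding * h[0], grid_size)
    y = np.linspace(pts[:, 1].min() - padding * h[1],
                    pts[:, 1].max() + padding * h[1], grid_size)
    # evaluate separably per point: N(x; px, hx) outer N(y; py, hy)
    gx = np.exp(-0.5 * ((x[None, :] - pts[:, 0:1]) / h[0]) ** 2) / (
        h[0] * np.sqrt(2 * np.pi)
    )
    gy = np.exp(-0.5 * ((y[None, :] - pts[:, 1:2]) / h[1]) ** 2) / (
        h[1] * np.sqrt(2 * np.pi)
    )
    density = (gy[:, :, None] * gx[:, None, :]).mean(axis=0)
    return x, y, density
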