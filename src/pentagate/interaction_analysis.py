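"""Electrostatic contacts, ion coordination, interface distances, bootstraps.

Distance criteria are heavy-atom cutoffs (no hydrogen geometry): a sodium
ion "coordinates" a glutamate when it is within 5 A of either carboxylate
oxygen; a salt bridge is any lysine side-chain nitrogen within 4 A of a
glutamate carboxylate oxygen.  Distances are plain Euclidean — protein-
internal measures are minimum-image safe in the systems analysed here.

Replicate summaries are percentile bootstrap medians with a seeded generator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .errors import InsufficientDataError, PairingError, SelectionError
from .structure_io import (
    CATION_RESNAMES,
    PentamerModel,
    Selection,
    TrajectoryFrameSet,
    resolve_selection,
    subunit_order,
)

DEFAULT_ION_CUTOFF = 5.0       # A, Na+ to carboxylate oxygen
DEFAULT_SALT_BRIDGE_CUTOFF = 4.0  # A, Lys N to Glu O
DEFAULT_STRIDE_NS = 10.0
DEFAULT_WINDOW_NS = 300.0      # analyse the final 300 ns of each replicate

#: Side-chain oxygen names of glutamate/aspartate carboxylates.
CARBOXYLATE_OXYGENS = ("OE1", "OE2", "OD1", "OD2")
#: Side-chain nitrogen names of lysine/arginine.
BASIC_NITROGENS = ("NZ", "NH1", "NH2", "NE")


@dataclass
class ContactSeries:
    """Per-frame, per-subunit contact or coordination values.

    ``values`` has shape ``(n_frames, n_subunits)``: integer counts for
    coordination series, 0/1 for boolean contacts.  ``pooled`` gives the
    per-frame value pooled over subunits (sum of counts).
    """

    frame_times: np.ndarray
    values: np.ndarray
    cutoff: float
    label: str = ""

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values))
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        if self.values.shape[0] != self.frame_times.shape[0]:
            raise PairingError("values length must equal frame count")
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")

    @property
    def pooled(self) -> np.ndarray:
        return self.values.sum(axis=1)


@dataclass(frozen=True)
class SummaryStat:
    """Bootstrap median with percentile confidence interval."""

    median: float
    ci_low: float
    ci_high: float
    n_samples: int
    level: float = 0.95
    n_boot: int = 10_000
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.median <= self.ci_high):
            raise ValueError("CI must bracket the median")


def _carboxylate_indices(model: PentamerModel, residue: int) -> dict[str, np.ndarray]:
    """Per-chain indices of side-chain carboxylate oxygens of a residue."""
    a = model.atoms
    out = {}
    for c in model.chains:
        m = (
            model.protein_mask
            & (a.chain_id == c)
            & (a.res_id == residue)
            & np.isin(a.atom_name, list(CARBOXYLATE_OXYGENS))
        )
        idx = np.flatnonzero(m)
        if idx.size == 0:
            res_names = set(a.res_name[(a.chain_id == c) & (a.res_id == residue)])
            raise SelectionError(
                f"residue {residue} chain {c} has no carboxylate oxygens "
                f"(residue type {res_names or 'absent'})"
            )
        out[c] = idx
    return out


def ion_coordination_series(
    traj: TrajectoryFrameSet,
    residue: int = 35,
    ion_name: str = "NA",
    cutoff: float = DEFAULT_ION_CUTOFF,
    stride_ns: float | None = DEFAULT_STRIDE_NS,
) -> ContactSeries:
    """Sodium ions within ``cutoff`` of the residue's carboxylate oxygens.

    Frames are sampled every ``stride_ns`` (None = every frame).  Each
    sampled frame yields, per subunit, the number of distinct ions within the
    cutoff (inclusive) of any carboxylate oxygen of that subunit's copy of
    the residue; the pooled per-frame value counts distinct ions near any
    copy.
    """
    model = traj.model
    ox = _carboxylate_indices(model, residue)
    a = model.atoms
    ion_idx = np.flatnonzero(
        np.isin(a.res_name, list(CATION_RESNAMES)) & (a.atom_name == ion_name)
    )
    if stride_ns is None or traj.n_frames <= 1:
        frames = np.arange(traj.n_frames)
    else:
        t0 = traj.times[0]
        keep, next_t = [], t0
        for i, t in enumerate(traj.times):
            if t >= next_t - 1e-9:
                keep.append(i)
                next_t = t + stride_ns
        frames = np.asarray(keep, dtype=int)
    values = np.zeros((frames.size, len(model.chains)), dtype=int)
    for k, fi in enumerate(frames):
        xyz = np.asarray(traj.coords[fi], dtype=float)
        if ion_idx.size == 0:
            continue
        ions = xyz[ion_idx]
        for ci, c in enumerate(model.chains):
            d = cdist(ions, xyz[ox[c]])
            values[k, ci] = int(np.any(d <= cutoff, axis=1).sum())
    return ContactSeries(
        frame_times=traj.times[frames],
        values=values,
        cutoff=cutoff,
        label=f"ion {ion_name} within {cutoff} A of residue {residue}",
    )


def min_group_distance(
    model: PentamerModel,
    group_a: Selection | np.ndarray,
    group_b: Selection | np.ndarray,
    coords: np.ndarray | None = None,
) -> float:
    """Minimum heavy-atom pairwise distance between two atom groups.

    Groups may be :class:`Selection` objects or explicit index arrays.
    """
    def _resolve(g):
        if isinstance(g, Selection):
            return resolve_selection(model, g)
        g = np.asarray(g, dtype=int)
        if g.size == 0:
            raise SelectionError("empty atom group")
        return g

    ia, ib = _resolve(group_a), _resolve(group_b)
    xyz = model.coord if coords is None else np.asarray(coords, dtype=float)
    return float(cdist(xyz[ia], xyz[ib]).min())


def contact_fraction(series, threshold: int = 1) -> float:
    """Fraction of samples with value >= threshold.

    Accepts a :class:`ContactSeries` (pooled over frame x subunit samples) or
    any array of per-frame values.
    """
    if isinstance(series, ContactSeries):
        values = series.values.ravel()
    else:
        values = np.asarray(series).ravel()
    if values.size == 0:
        raise InsufficientDataError("empty contact series")
    return float(np.mean(values >= threshold))


def salt_bridge_series(
    traj: TrajectoryFrameSet,
    acid_residue: int = 243,
    base_residue: int = 248,
    cutoff: float = DEFAULT_SALT_BRIDGE_CUTOFF,
) -> ContactSeries:
    """Intrasubunit acid-base contact per frame per subunit (0/1).

    Contact = any basic side-chain nitrogen of ``base_residue`` within
    ``cutoff`` of any carboxylate oxygen of ``acid_residue`` on the same
    subunit (the M2/M2-M3 pairing of E243 with K248 by default).
    """
    model = traj.model
    a = model.atoms
    ox = _carboxylate_indices(model, acid_residue)
    nz = {}
    for c in model.chains:
        m = (
            model.protein_mask
            & (a.chain_id == c)
            & (a.res_id == base_residue)
            & np.isin(a.atom_name, list(BASIC_NITROGENS))
        )
        idx = np.flatnonzero(m)
        if idx.size == 0:
            raise SelectionError(
                f"residue {base_residue} chain {c} has no basic side-chain nitrogens"
            )
        nz[c] = idx
    values = np.zeros((traj.n_frames, len(model.chains)), dtype=int)
    for fi in range(traj.n_frames):
        xyz = np.asarray(traj.coords[fi], dtype=float)
        for ci, c in enumerate(model.chains):
            d = cdist(xyz[nz[c]], xyz[ox[c]])
            values[fi, ci] = int(d.min() <= cutoff)
    return ContactSeries(
        frame_times=traj.times,
        values=values,
        cutoff=cutoff,
        label=f"contact {acid_residue}-{base_residue} <= {cutoff} A",
    )


def intersubunit_ca_distance(
    model: PentamerModel,
    res_a: int = 35,
    res_b: int = 158,
    coords: np.ndarray | None = None,
    axis=None,
) -> np.ndarray:
    """C-alpha distance from residue ``res_a`` on each principal subunit to
    residue ``res_b`` on its complementary (next counterclockwise) subunit,
    for all five interfaces.  Returns shape (5,)."""
    from .pore_geometry import estimate_pore_axis

    if axis is None:
        axis = estimate_pore_axis(model)
    order = subunit_order(model, axis)
    xyz = model.coord if coords is None else np.asarray(coords, dtype=float)
    try:
        ia = [model.atom_index(c, res_a, "CA") for c in order]
        ib = [model.atom_index(c, res_b, "CA") for c in order]
    except SelectionError as exc:
        raise PairingError(f"missing C-alpha for interface distance: {exc}") from exc
    out = np.empty(5)
    for i in range(5):
        out[i] = np.linalg.norm(xyz[ia[i]] - xyz[ib[(i + 1) % 5]])
    return out


def intersubunit_ca_distance_series(
    traj: TrajectoryFrameSet, res_a: int = 35, res_b: int = 158
) -> np.ndarray:
    """Per-frame interface distances, shape (n_frames, 5)."""
    out = np.empty((traj.n_frames, 5))
    for i in range(traj.n_frames):
        frame = traj.frame_model(i)
        out[i] = intersubunit_ca_distance(frame, res_a, res_b)
    return out


def bootstrap_median_ci(
    samples,
    level: float = 0.95,
    n_boot: int = 10_000,
    seed: int | None = None,
) -> SummaryStat:
    """Percentile-bootstrap confidence interval of the median.

    Resampling uses ``numpy.random.default_rng(seed).integers(0, n, (n_boot,
    n))``; percentiles via ``numpy.percentile`` (linear interpolation).
    Deterministic given the seed.
    """
    x = np.asarray(samples, dtype=float).ravel()
    if x.size == 0:
        raise InsufficientDataError("no samples for bootstrap")
    if not (0 < level < 1):
        raise ValueError("level must be in (0, 1)")
    med = float(np.median(x))
    if x.size == 1 or np.ptp(x) == 0:
        return SummaryStat(med, med, med, x.size, level, n_boot, seed)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, x.size, size=(n_boot, x.size))
    boot_medians = np.median(x[idx], axis=1)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.percentile(boot_medians, [100 * alpha, 100 * (1 - alpha)])
    # the interval is for the median; make sure it brackets the point estimate
    lo, hi = min(float(lo), med), max(float(hi), med)
    return SummaryStat(med, lo, hi, x.size, level, n_boot, seed)
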