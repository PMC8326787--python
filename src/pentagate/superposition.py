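"""Rigid-body least-squares superposition (Kabsch) and restricted RMSD.

All atoms are weighted equally; the analyses here operate on C-alpha
selections where mass differences are negligible.  Chain correspondence
between two pentamers is established by azimuthal subunit order with the
cyclic offset that minimises the fitted RMSD, since deposited chain labels
need not correspond.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import GeometryError, PairingError
from .structure_io import PentamerModel, Selection, TrajectoryFrameSet, resolve_selection

# Alignment ranges for the extracellular and transmembrane domains, and the
# flexible loops excluded from "non-loop" backbone comparisons (beta1-beta2,
# loop F, M2-M3).  The loop exclusions are configuration, not dogma.
ECD_ALIGN_RANGE = (17, 192)
TMD_ALIGN_RANGE = (196, 314)
ECD_RMSD_RANGES = ((15, 48), (66, 192))
TMD_RMSD_RANGE = (197, 313)
DEFAULT_LOOP_EXCLUSIONS = ((30, 36), (151, 160), (243, 250))


def nonloop_ca_selection(
    loop_exclusions=DEFAULT_LOOP_EXCLUSIONS,
) -> Selection:
    """C-alpha selection over both domains minus flexible-loop intervals."""
    sel = Selection.ca(ECD_ALIGN_RANGE, TMD_ALIGN_RANGE)
    return sel.subtract(loop_exclusions)


@dataclass(frozen=True)
class FitResult:
    """Least-squares rigid fit: ``fitted = mobile @ rotation.T + translation``."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    n_atoms: int

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def kabsch_fit(mobile: np.ndarray, reference: np.ndarray) -> FitResult:
    """Optimal proper rotation + translation of ``mobile`` onto ``reference``.

    Closed-form SVD solution; reflections are excluded by construction.
    Raises :class:`GeometryError` for fewer than three atoms; collinear point
    sets yield a conditioning warning but still return a result.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise PairingError(
            f"coordinate shapes differ: {mobile.shape} vs {reference.shape}"
        )
    n = mobile.shape[0]
    if n < 3:
        raise GeometryError(f"need >= 3 atoms for superposition, got {n}")
    mob_c = mobile.mean(axis=0)
    ref_c = reference.mean(axis=0)
    h = (mobile - mob_c).T @ (reference - ref_c)
    u, s, vt = np.linalg.svd(h)
    if s[1] <= 1e-8 * max(s[0], 1.0):
        warnings.warn(
            "near-collinear point set: rotation is ill-conditioned", stacklevel=2
        )
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    translation = ref_c - rot @ mob_c
    fitted = mobile @ rot.T + translation
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - reference) ** 2, axis=1))))
    return FitResult(rot, translation, rmsd, n)


def _selection_keys(model: PentamerModel, idx: np.ndarray) -> list[tuple[int, str]]:
    a = model.atoms
    return [(int(r), n) for r, n in zip(a.res_id[idx], a.atom_name[idx])]


def _per_chain_blocks(model: PentamerModel, sel: Selection, order: list[str]):
    """Resolved indices per chain, in the given chain order, symmetric-dropped."""
    idx = resolve_selection(model, sel, symmetric="drop")
    cid = model.atoms.chain_id[idx]
    blocks = [idx[cid == c] for c in order]
    if any(b.size == 0 for b in blocks):
        raise PairingError("a chain resolves no atoms for the selection")
    return blocks


def rmsd_between_models(
    a: PentamerModel,
    b: PentamerModel,
    fit_sel: Selection,
    measure_sel: Selection | None = None,
) -> float:
    """RMSD over ``measure_sel`` after superposing on ``fit_sel``.

    Chain correspondence uses azimuthal subunit order on each model with the
    cyclic offset minimising the fitted RMSD; symmetric in its two model
    arguments to numerical precision.
    """
    from .pore_geometry import estimate_pore_axis
    from .structure_io import subunit_order

    if measure_sel is None:
        measure_sel = fit_sel
    order_a = subunit_order(a, estimate_pore_axis(a))
    order_b = subunit_order(b, estimate_pore_axis(b))

    fit_a = _per_chain_blocks(a, fit_sel, order_a)
    mea_a = _per_chain_blocks(a, measure_sel, order_a)

    best = None
    for shift in range(5):
        order_b_s = order_b[shift:] + order_b[:shift]
        fit_b = _per_chain_blocks(b, fit_sel, order_b_s)
        mea_b = _per_chain_blocks(b, measure_sel, order_b_s)
        for blocks_x, blocks_y, model_x, model_y in (
            (fit_a, fit_b, a, b), (mea_a, mea_b, a, b)
        ):
            for bx, by in zip(blocks_x, blocks_y):
                kx = _selection_keys(model_x, bx)
                ky = _selection_keys(model_y, by)
                if kx != ky:
                    first = next(
                        (p for p, q in zip(kx, ky) if p != q),
                        (kx[len(ky):] or ky[len(kx):] or ["<length>"])[0],
                    )
                    raise PairingError(
                        f"selection identity mismatch between models near {first}"
                    )
        xa = a.coord[np.concatenate(fit_a)]
        xb = b.coord[np.concatenate(fit_b)]
        fit = kabsch_fit(xb, xa)
        ma = a.coord[np.concatenate(mea_a)]
        mb = fit.apply(b.coord[np.concatenate(mea_b)])
        rmsd = float(np.sqrt(np.mean(np.sum((mb - ma) ** 2, axis=1))))
        if best is None or rmsd < best:
            best = rmsd
    return best


def per_frame_rmsd(
    traj: TrajectoryFrameSet,
    reference: PentamerModel,
    fit_sel: Selection,
    measure_sel: Selection | None = None,
) -> np.ndarray:
    """RMSD of each frame to a reference model (fit on ``fit_sel``,
    measured on ``measure_sel``); returns one value per frame, Angstrom.

    The trajectory topology must resolve the selections identically to the
    reference (same residue/atom identity per chain).
    """
    if measure_sel is None:
        measure_sel = fit_sel
    fit_ref = resolve_selection(reference, fit_sel, symmetric="drop")
    mea_ref = resolve_selection(reference, measure_sel, symmetric="drop")
    fit_top = resolve_selection(traj.model, fit_sel, symmetric="drop")
    mea_top = resolve_selection(traj.model, measure_sel, symmetric="drop")
    for ref_idx, top_idx in ((fit_ref, fit_top), (mea_ref, mea_top)):
        kr = _selection_keys(reference, ref_idx)
        kt = _selection_keys(traj.model, top_idx)
        if kr != kt:
            first = next((p for p, q in zip(kr, kt) if p != q), "<length>")
            raise PairingError(
                f"trajectory/reference selection mismatch near {first}"
            )
    ref_fit = reference.coord[fit_ref]
    ref_mea = reference.coord[mea_ref]
    out = np.empty(traj.n_frames)
    for i in range(traj.n_frames):
        frame = np.asarray(traj.coords[i], dtype=float)
        fit = kabsch_fit(frame[fit_top], ref_fit)
        moved = fit.apply(frame[mea_top])
        out[i] = np.sqrt(np.mean(np.sum((moved - ref_mea) ** 2, axis=1)))
    return out
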