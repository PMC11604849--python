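"""Voxelwise variable-projection (VARPRO) estimation of water/fat parameters.

For each voxel the complex multi-echo signal is modelled as
``y = Psi A x e^{i phi}`` with real linear amplitudes
``x = (W, Fntg, Fndb, Fnmidb)``, off-resonance phase matrix
``Psi = diag(e^{i 2 pi psi t_n})`` and the N x 4 complex basis ``A``
(water + fat subcomponent time courses at a given R2*).  The linear
amplitudes and the initial phase have closed forms:

* ``x_hat  = Re(A^H A)^{-1} Re(A^H Psi^H y e^{-i phi})``
* ``phi_hat = 1/2 arg( (A^H Psi^H y)^T Re(A^H A)^{-1} (A^H Psi^H y) )``

leaving a residual J(psi, R2*) that is minimised on a discrete grid
(R2* 0..300 1/s in steps of 2 by exhaustive per-psi minimisation; psi
over one aliasing bandwidth), with spatial smoothness of the
off-resonance map imposed by a multiresolution iterated-conditional-
modes (ICM) scheme to avoid water-fat swaps.  A final two-stage bounded
fit refines the amplitudes: stage 1 folds Fnmidb into Fndb through an
assumed nmidb/ndb ratio, stage 2 re-solves with every component bounded
to [0.5, 2] times its initial estimate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import lsq_linear

from .triglyceride_model import (
    SpectralConstants,
    TriglycerideComposition,
    basis_matrix,
    fac_from_subcomponents,
)

logger = logging.getLogger("facmri")

__all__ = [
    "FitConfig",
    "VoxelFit",
    "linear_solve",
    "optimal_phase",
    "residual",
    "confounder_search",
    "refine_confounders",
    "two_stage_fit",
    "fit_image",
    "fac_maps_from_fits",
]


@dataclass(frozen=True)
class FitConfig:
    """Grids, bounds and smoothness settings of the voxelwise fit.

    ``psi_grid`` defaults to +/- half the amplitude-aliasing bandwidth
    of the effective echo spacing (for 0.9 ms, about +/-555 Hz) in 2 Hz
    steps; ``r2star_grid`` to 0..300 1/s in steps of 2.
    """

    r2star_grid: np.ndarray = field(
        default_factory=lambda: np.arange(0.0, 302.0, 2.0))
    psi_grid: np.ndarray = None
    nmidb_to_ndb_ratio: float = 0.26
    cl: float = 17.4
    bound_factors: tuple = (0.5, 2.0)
    smoothness_weight: float = 0.5
    smoothness_cap_hz: float = 80.0
    icm_sweeps: int = 12
    subgrid_refine: bool = True   # parabolic psi/R2* refinement between grid points
    local_window_hz: float = 20.0  # post-ICM per-voxel re-pick window

    def __post_init__(self):
        if self.psi_grid is None:
            object.__setattr__(self, "psi_grid", np.arange(-556.0, 557.0, 2.0))
        if len(self.r2star_grid) == 0 or len(self.psi_grid) == 0:
            raise ValueError("parameter grids must be non-empty")
        lo, hi = self.bound_factors
        if not 0 < lo <= hi:
            raise ValueError("bound factors must be positive and ordered")

    def assumed_composition(self) -> TriglycerideComposition:
        """Assumed mean triglyceride for the basis and its normalisation.

        The ndb magnitude matters through the proton-density scale of
        the fat columns; absent other knowledge it is taken consistent
        with the chain-length heuristic ``cl = 16.8 + 0.25 ndb``
        (cl 17.4 -> ndb 2.4), with nmidb from the configured ratio.
        """
        ndb_ref = max((self.cl - 16.8) / 0.25, 0.5)
        return TriglycerideComposition(
            cl=self.cl, ndb=ndb_ref, nmidb=self.nmidb_to_ndb_ratio * ndb_ref)


@dataclass
class VoxelFit:
    """Per-voxel fit result: amplitudes, confounders and diagnostic flags."""

    x: np.ndarray                 # (W, Fntg, Fndb, Fnmidb)
    psi_hz: float
    r2star: float
    phi_rad: float
    residual: float
    masked: bool = False
    boundary: bool = False
    sign_restored: bool = False


# ---------------------------------------------------------------------------
# Closed-form solutions for fixed confounders
# ---------------------------------------------------------------------------


def _phase_ramp(te: np.ndarray, psi: float) -> np.ndarray:
    return np.exp(2j * np.pi * psi * te)


def linear_solve(y: np.ndarray, basis: np.ndarray, psi: float, phi: float,
                 te: np.ndarray) -> np.ndarray:
    """Real-valued least-squares amplitudes for fixed (psi, R2*, phi).

    ``x = Re(A^H A)^{-1} Re(A^H Psi^H y e^{-i phi})``.  Raises
    ``numpy.linalg.LinAlgError`` for a singular normal matrix; callers
    treat that as a masked voxel.
    """
    a = basis
    r = np.real(a.conj().T @ a)
    z = a.conj().T @ (np.conj(_phase_ramp(te, psi)) * y)
    return np.linalg.solve(r, np.real(z * np.exp(-1j * phi)))


def optimal_phase(y: np.ndarray, basis: np.ndarray, psi: float,
                  te: np.ndarray) -> float:
    """Analytic initial phase minimising the residual for fixed (psi, R2*).

    ``phi = 1/2 arg( z^T Re(A^H A)^{-1} z )`` with ``z = A^H Psi^H y``.
    The half-argument leaves a pi ambiguity that corresponds to negating
    x; the returned value lies in (-pi/2, pi/2] and callers canonicalise
    the branch by requiring Fntg >= 0.
    """
    a = basis
    z = a.conj().T @ (np.conj(_phase_ramp(te, psi)) * y)
    if np.allclose(z, 0):
        return 0.0
    r = np.real(a.conj().T @ a)
    w = z @ np.linalg.solve(r, z)
    phi = 0.5 * np.angle(w)
    if phi <= -np.pi / 2:
        phi += np.pi
    elif phi > np.pi / 2:
        phi -= np.pi
    return phi


def residual(y: np.ndarray, basis: np.ndarray, psi: float, phi: float,
             te: np.ndarray) -> float:
    """Squared projection residual ``J = ||y - Psi A x_hat e^{i phi}||^2``."""
    x = linear_solve(y, basis, psi, phi, te)
    model = _phase_ramp(te, psi) * (basis @ x) * np.exp(1j * phi)
    return float(np.sum(np.abs(y - model) ** 2))


# ---------------------------------------------------------------------------
# Whole-image confounder search
# ---------------------------------------------------------------------------


def _residual_grid(y_flat: np.ndarray, te: np.ndarray, cfg: FitConfig,
                   consts: SpectralConstants,
                   comp: TriglycerideComposition) -> tuple:
    """J minimised over R2* for every (psi grid point, voxel).

    Returns ``(j_psi, r2_idx)`` with shapes (n_psi, V): the per-psi
    minimal residual and the index of the minimising R2* grid point.
    Fully vectorised: for each R2* the 4 x N adjoint basis and the
    4 x 4 inverse normal matrix are precomputed; for each psi the
    demodulated data are shared across all R2* values.
    """
    n_te = te.size
    v = y_flat.shape[1]
    r2_grid = np.asarray(cfg.r2star_grid)
    psi_grid = np.asarray(cfg.psi_grid)
    n_r2, n_psi = r2_grid.size, psi_grid.size

    ah = np.empty((n_r2, 4, n_te), dtype=complex)
    minv = np.empty((n_r2, 4, 4))
    for k, r2 in enumerate(r2_grid):
        a = basis_matrix(te, comp, r2, consts)
        ah[k] = a.conj().T
        minv[k] = np.linalg.inv(np.real(a.conj().T @ a))
    ah_flat = ah.reshape(n_r2 * 4, n_te)

    ynorm = np.sum(np.abs(y_flat) ** 2, axis=0)          # (V,)
    j_psi = np.empty((n_psi, v), dtype=np.float64)
    r2_idx = np.empty((n_psi, v), dtype=np.uint16)
    for p, psi in enumerate(psi_grid):
        ypsi = np.conj(_phase_ramp(te, psi))[:, None] * y_flat     # (N, V)
        z = (ah_flat @ ypsi).reshape(n_r2, 4, v)                    # (R, 4, V)
        mz = np.einsum("rab,rbv->rav", minv, z)
        w = np.einsum("rav,rav->rv", z, mz)           # z^T M z (no conjugate)
        phi = 0.5 * np.angle(w)
        u = np.real(z * np.exp(-1j * phi)[:, None, :])
        mu = np.einsum("rab,rbv->rav", minv, u)
        j = ynorm[None, :] - np.einsum("rav,rav->rv", u, mu)
        k_best = np.argmin(j, axis=0)
        j_psi[p] = j[k_best, np.arange(v)]
        r2_idx[p] = k_best.astype(np.uint16)
    return j_psi, r2_idx


def _j_fixed_basis(yd: np.ndarray, a: np.ndarray) -> np.ndarray:
    """Residual J for demodulated voxels (N, V) under a fixed basis."""
    z = a.conj().T @ yd
    minv = np.linalg.inv(np.real(a.conj().T @ a))
    w = np.einsum("av,ab,bv->v", z, minv, z)
    phi = 0.5 * np.angle(w)
    u = np.real(z * np.exp(-1j * phi)[None, :])
    return (np.sum(np.abs(yd) ** 2, axis=0)
            - np.einsum("av,ab,bv->v", u, minv, u))


def _polish_r2(y_sel: np.ndarray, te: np.ndarray, psi_sel: np.ndarray,
               r2_sel: np.ndarray, cfg: FitConfig, consts: SpectralConstants,
               comp: TriglycerideComposition) -> np.ndarray:
    """Parabolic sub-grid refinement of R2* at fixed (per-voxel) psi."""
    grid = np.asarray(cfg.r2star_grid)
    if grid.size < 2:
        return r2_sel
    step = float(grid[1] - grid[0])
    yd = np.exp(-2j * np.pi * np.outer(te, psi_sel)) * y_sel
    j3 = np.full((3, r2_sel.size), np.nan)
    for val in np.unique(r2_sel):
        cols = np.where(r2_sel == val)[0]
        for i, d in enumerate((-step, 0.0, step)):
            r2v = val + d
            if r2v < grid[0] or r2v > grid[-1]:
                continue
            a = basis_matrix(te, comp, r2v, consts)
            j3[i, cols] = _j_fixed_basis(yd[:, cols], a)
    jm, j0, jp = j3
    den = jm - 2.0 * j0 + jp
    with np.errstate(divide="ignore", invalid="ignore"):
        delta = 0.5 * (jm - jp) / den
    ok = np.isfinite(delta) & (den > 0)
    delta = np.where(ok, np.clip(delta, -1.0, 1.0), 0.0)
    return r2_sel + delta * step


def _icm_labels(j_norm: np.ndarray, psi_grid: np.ndarray, shape: tuple,
                weight: float, cap_hz: float, sweeps: int,
                init_labels: np.ndarray = None) -> np.ndarray:
    """Iterated conditional modes over discrete psi labels.

    Minimises ``sum_v Jn(v, l_v) + weight * sum_{v~u} min(|psi_l_v -
    psi_l_u|, cap)/cap`` on the 4-neighbour grid.  ``j_norm`` has shape
    (n_psi, ny*nx) and should be normalised per voxel so the data and
    smoothness terms are commensurate.
    """
    ny, nx = shape
    n_psi = psi_grid.size
    labels = (np.argmin(j_norm, axis=0) if init_labels is None
              else init_labels.copy()).reshape(ny, nx)
    jn = j_norm.reshape(n_psi, ny, nx)
    for _ in range(sweeps):
        changed = 0
        psi_map = psi_grid[labels]
        # neighbour psi values with edge replication
        nb = np.stack([
            np.vstack([psi_map[:1], psi_map[:-1]]),
            np.vstack([psi_map[1:], psi_map[-1:]]),
            np.hstack([psi_map[:, :1], psi_map[:, :-1]]),
            np.hstack([psi_map[:, 1:], psi_map[:, -1:]]),
        ])                                               # (4, ny, nx)
        pen = np.minimum(
            np.abs(psi_grid[:, None, None, None] - nb[None]), cap_hz
        ).sum(axis=1) / cap_hz                           # (n_psi, ny, nx)
        cost = jn + weight * pen
        new_labels = np.argmin(cost, axis=0)
        changed = int(np.sum(new_labels != labels))
        # checkerboard update keeps ICM stable on a grid
        parity = (np.add.outer(np.arange(ny), np.arange(nx)) % 2).astype(bool)
        labels[parity] = new_labels[parity]
        psi_map = psi_grid[labels]
        nb = np.stack([
            np.vstack([psi_map[:1], psi_map[:-1]]),
            np.vstack([psi_map[1:], psi_map[-1:]]),
            np.hstack([psi_map[:, :1], psi_map[:, :-1]]),
            np.hstack([psi_map[:, 1:], psi_map[:, -1:]]),
        ])
        pen = np.minimum(
            np.abs(psi_grid[:, None, None, None] - nb[None]), cap_hz
        ).sum(axis=1) / cap_hz
        cost = jn + weight * pen
        new_labels = np.argmin(cost, axis=0)
        labels[~parity] = new_labels[~parity]
        if changed == 0:
            break
    return labels


def confounder_search(images, cfg: FitConfig, consts: SpectralConstants,
                      comp_assumed: TriglycerideComposition = None,
                      mask: np.ndarray = None) -> tuple:
    """Off-resonance and R2* maps from the denoised echo series.

    The residual J is evaluated on the discrete (psi, R2*) grid with R2*
    marginalised by its per-psi minimum; the psi label field is then
    chosen by a coarse-to-fine ICM optimisation penalising neighbour
    differences (capped absolute difference), which resolves the
    water-fat ambiguity.  With ``smoothness_weight == 0`` each voxel
    independently takes its global grid minimiser.

    Returns ``(psi_map, r2star_map, j_map, boundary_flags)``.
    """
    imgs = images.images if hasattr(images, "images") else np.asarray(images)
    te = np.asarray(images.design.te_list) if hasattr(images, "design") else None
    if te is None:
        raise ValueError("images must carry an AcquisitionDesign")
    n_te, ny, nx = imgs.shape
    if comp_assumed is None:
        comp_assumed = cfg.assumed_composition()
    y_flat = imgs.reshape(n_te, -1)
    psi_grid = np.asarray(cfg.psi_grid)
    r2_grid = np.asarray(cfg.r2star_grid)
    if mask is not None:
        # residual grid only where it matters; background gets a flat term
        sel = mask.reshape(-1)
        j_sub, r2_sub = _residual_grid(y_flat[:, sel], te, cfg, consts,
                                       comp_assumed)
        j_psi = np.zeros((psi_grid.size, y_flat.shape[1]))
        r2_idx = np.zeros((psi_grid.size, y_flat.shape[1]), dtype=np.uint16)
        j_psi[:, sel] = j_sub
        r2_idx[:, sel] = r2_sub
    else:
        j_psi, r2_idx = _residual_grid(y_flat, te, cfg, consts, comp_assumed)

    if cfg.smoothness_weight <= 0:
        labels = np.argmin(j_psi, axis=0).reshape(ny, nx)
    else:
        ynorm = np.sum(np.abs(y_flat) ** 2, axis=0)
        floor = 1e-12 * max(ynorm.max(), 1e-300)
        j_norm = j_psi / np.maximum(ynorm, floor)[None, :]
        if mask is not None:
            # outside the object any label is fine; flatten the data term
            j_norm[:, ~mask.reshape(-1)] = 0.0
        # coarse-to-fine pyramid: region-level swaps are resolved at the
        # coarse scales where a vial-sized region is only a few blocks
        init_full = None
        for factor in (4, 2, 1):
            cy, cx = ny // factor, nx // factor
            if factor > 1 and (cy < 4 or cx < 4):
                continue
            jc = j_norm.reshape(-1, ny, nx)[:, :factor * cy, :factor * cx]
            jc = jc.reshape(-1, cy, factor, cx, factor).mean(axis=(2, 4))
            init_lvl = None
            if init_full is not None:
                init_lvl = init_full[:factor * cy:factor,
                                     :factor * cx:factor].reshape(-1)
            labels = _icm_labels(jc.reshape(-1, cy * cx), psi_grid, (cy, cx),
                                 cfg.smoothness_weight, cfg.smoothness_cap_hz,
                                 cfg.icm_sweeps, init_labels=init_lvl)
            up = np.repeat(np.repeat(labels, factor, axis=0), factor, axis=1)
            init_full = np.pad(
                up, ((0, ny - factor * cy), (0, nx - factor * cx)), mode="edge")
        labels = init_full
    flat_labels = labels.reshape(-1)
    cols = np.arange(flat_labels.size)
    if cfg.local_window_hz > 0 and psi_grid.size > 1:
        # the smoothness term resolves the aliased branch but flattens
        # steep gradients; re-pick each voxel's label from the residuals
        # within a local window around the ICM label
        step = float(psi_grid[1] - psi_grid[0])
        k = max(1, int(round(cfg.local_window_hz / step)))
        lo = np.maximum(flat_labels - k, 0)
        offsets = np.arange(2 * k + 1)
        idx = np.minimum(lo[None, :] + offsets[:, None], psi_grid.size - 1)
        window_j = j_psi[idx, cols[None, :]]
        flat_labels = idx[np.argmin(window_j, axis=0), cols]
        labels = flat_labels.reshape(ny, nx)
    psi_map = psi_grid[labels].astype(float)
    if cfg.subgrid_refine:
        # parabolic interpolation of J through the chosen label and its
        # neighbours recovers off-grid psi to well below the grid step
        inner = (flat_labels > 0) & (flat_labels < psi_grid.size - 1)
        lm, l0, lp = flat_labels - 1, flat_labels, flat_labels + 1
        lm[~inner] = l0[~inner]
        lp[~inner] = l0[~inner]
        jm, j0, jp = (j_psi[lab, cols] for lab in (lm, l0, lp))
        denom = jm - 2.0 * j0 + jp
        with np.errstate(divide="ignore", invalid="ignore"):
            delta = 0.5 * (jm - jp) / denom
        delta = np.where(np.isfinite(delta) & inner, np.clip(delta, -1, 1), 0.0)
        step = float(psi_grid[1] - psi_grid[0]) if psi_grid.size > 1 else 0.0
        psi_map = psi_map + (delta * step).reshape(ny, nx)
    r2_map = r2_grid[r2_idx[flat_labels, cols]].reshape(ny, nx).astype(float)
    j_map = j_psi[flat_labels, cols].reshape(ny, nx)
    boundary = ((labels == 0) | (labels == psi_grid.size - 1)
                | (r2_idx[flat_labels, cols].reshape(ny, nx) == r2_grid.size - 1))
    if cfg.subgrid_refine:
        sel = mask.reshape(-1) if mask is not None else np.ones(ny * nx, bool)
        r2_flat = r2_map.reshape(-1)
        r2_flat[sel] = _polish_r2(y_flat[:, sel], te,
                                  psi_map.reshape(-1)[sel], r2_flat[sel],
                                  cfg, consts, comp_assumed)
    return psi_map, r2_map, j_map, boundary


def refine_confounders(images, psi_init: np.ndarray, cfg: FitConfig,
                       consts: SpectralConstants,
                       comp_assumed: TriglycerideComposition,
                       mask: np.ndarray = None,
                       halfwidth_hz: float = 30.0) -> tuple:
    """Local (psi, R2*) re-minimisation around an existing field map.

    After a global search has fixed the smooth off-resonance map (and
    resolved the water-fat ambiguity), the confounders can be
    re-estimated with a different composition assumption — e.g. a
    phantom oil's known chain length — by demodulating each voxel with
    its current psi and searching a narrow offset window that excludes
    the aliased decoys.  Returns refined ``(psi_map, r2star_map)``.
    """
    imgs = images.images
    te = np.asarray(images.design.te_list)
    n_te, ny, nx = imgs.shape
    if mask is None:
        mask = np.ones((ny, nx), dtype=bool)
    sel = mask.reshape(-1)
    y = imgs.reshape(n_te, -1)[:, sel]
    psi0 = psi_init.reshape(-1)[sel]
    y_demod = np.exp(-2j * np.pi * np.outer(te, psi0)) * y
    step = float(cfg.psi_grid[1] - cfg.psi_grid[0]) if len(cfg.psi_grid) > 1 else 2.0
    offsets = np.arange(-halfwidth_hz, halfwidth_hz + step / 2, step)
    local = FitConfig(r2star_grid=cfg.r2star_grid, psi_grid=offsets,
                      nmidb_to_ndb_ratio=cfg.nmidb_to_ndb_ratio, cl=cfg.cl,
                      smoothness_weight=0.0, subgrid_refine=cfg.subgrid_refine)
    j_psi, r2_idx = _residual_grid(y_demod, te, local, consts, comp_assumed)
    lab = np.argmin(j_psi, axis=0)
    cols = np.arange(lab.size)
    delta = offsets[lab].astype(float)
    if cfg.subgrid_refine and offsets.size > 2:
        inner = (lab > 0) & (lab < offsets.size - 1)
        lm = np.where(inner, lab - 1, lab)
        lp = np.where(inner, lab + 1, lab)
        jm, j0, jp = (j_psi[l, cols] for l in (lm, lab, lp))
        den = jm - 2.0 * j0 + jp
        with np.errstate(divide="ignore", invalid="ignore"):
            sub = 0.5 * (jm - jp) / den
        sub = np.where(np.isfinite(sub) & inner, np.clip(sub, -1, 1), 0.0)
        delta = delta + sub * step
    psi_out = psi_init.astype(float).copy()
    psi_out.reshape(-1)[sel] = psi0 + delta
    r2_out = np.zeros((ny, nx))
    r2_sel = np.asarray(cfg.r2star_grid, dtype=float)[r2_idx[lab, cols]]
    if cfg.subgrid_refine:
        r2_sel = _polish_r2(y, te, psi0 + delta, r2_sel, cfg, consts,
                            comp_assumed)
    r2_out.reshape(-1)[sel] = r2_sel
    return psi_out, r2_out


# ---------------------------------------------------------------------------
# Two-stage bounded amplitude fit
# ---------------------------------------------------------------------------


def two_stage_fit(y: np.ndarray, psi: float, r2star: float, cfg: FitConfig,
                  consts: SpectralConstants, te: np.ndarray,
                  comp_assumed: TriglycerideComposition = None) -> VoxelFit:
    """Bounded two-stage amplitude estimate for one voxel.

    Stage 1 solves the simplified 3-component model in which the Fnmidb
    column is folded into the Fndb column with the assumed nmidb/ndb
    ratio, giving initial estimates (and an initial Fnmidb as ratio x
    Fndb).  Stage 2 re-solves the full 4-component real linear system
    with every amplitude restricted to [0.5, 2] times its initial
    estimate (bounds taken on magnitudes with signs restored, flagged
    when an initial component is negative), using a trust-region
    bounded least-squares solver.
    """
    if comp_assumed is None:
        comp_assumed = cfg.assumed_composition()
    if np.allclose(y, 0):
        return VoxelFit(x=np.zeros(4), psi_hz=psi, r2star=r2star,
                        phi_rad=0.0, residual=0.0, masked=True)
    a = basis_matrix(te, comp_assumed, r2star, consts)
    ratio = cfg.nmidb_to_ndb_ratio
    a3 = np.stack([a[:, 0], a[:, 1], a[:, 2] + ratio * a[:, 3]], axis=1)

    ramp = _phase_ramp(te, psi)
    yd = np.conj(ramp) * y

    # initial phase from the full 4-component model, then held fixed
    phi = optimal_phase(y, a, psi, te)

    # stage 1: closed-form 3-parameter solve at that phase
    z3 = a3.conj().T @ yd
    r3 = np.real(a3.conj().T @ a3)
    x3 = np.linalg.solve(r3, np.real(z3 * np.exp(-1j * phi)))
    if x3[1] < 0:      # canonical branch: Fntg >= 0
        phi += np.pi if phi <= 0 else -np.pi
        x3 = -x3
    x0 = np.array([x3[0], x3[1], x3[2], ratio * x3[2]])

    # stage 2: bounded linear least squares on the full 4-component model
    lo_f, hi_f = cfg.bound_factors
    mag = np.abs(x0)
    sign = np.where(x0 >= 0, 1.0, -1.0)
    lower = np.where(sign > 0, lo_f * mag, -hi_f * mag)
    upper = np.where(sign > 0, hi_f * mag, -lo_f * mag)
    degenerate = mag < 1e-30
    lower[degenerate], upper[degenerate] = -1e-30, 1e-30
    # complex residual stacked as real system: [Re; Im](A x) = [Re; Im](yd e^{-i phi})
    design_mat = np.vstack([np.real(a), np.imag(a)])
    rhs = np.concatenate([np.real(yd * np.exp(-1j * phi)),
                          np.imag(yd * np.exp(-1j * phi))])
    sol = lsq_linear(design_mat, rhs, bounds=(lower, upper),
                     method="trf", tol=1e-12)
    x = sol.x
    model = ramp * (a @ x) * np.exp(1j * phi)
    j = float(np.sum(np.abs(y - model) ** 2))
    at_bound = bool(np.any(np.isclose(x, lower, rtol=1e-6, atol=1e-30)
                           | np.isclose(x, upper, rtol=1e-6, atol=1e-30)))
    return VoxelFit(x=x, psi_hz=psi, r2star=r2star, phi_rad=phi,
                    residual=j, boundary=at_bound,
                    sign_restored=bool(np.any(sign < 0)))


def fit_image(images, cfg: FitConfig, consts: SpectralConstants,
              comp_assumed: TriglycerideComposition = None,
              mask: np.ndarray = None, progress: bool = False,
              confounders: tuple = None) -> dict:
    """Confounder search followed by the two-stage fit at every voxel.

    Returns a dict of maps: ``x`` (4, ny, nx), ``psi``, ``r2star``,
    ``phi``, ``residual`` and boolean flags ``masked``/``boundary``.
    ``confounders`` may supply precomputed ``(psi_map, r2star_map)``
    (e.g. shared across fits with different composition assumptions).
    Deterministic given its inputs; individual voxel failures are
    flagged, never fatal.
    """
    imgs = images.images
    te = np.asarray(images.design.te_list)
    n_te, ny, nx = imgs.shape
    if comp_assumed is None:
        comp_assumed = cfg.assumed_composition()
    if confounders is not None:
        psi_map, r2_map = confounders
        boundary = np.zeros((ny, nx), dtype=bool)
    else:
        psi_map, r2_map, _, boundary = confounder_search(
            images, cfg, consts, comp_assumed, mask=mask)
    x_map = np.zeros((4, ny, nx))
    phi_map = np.zeros((ny, nx))
    res_map = np.zeros((ny, nx))
    masked = np.zeros((ny, nx), dtype=bool)
    bnd = boundary.copy()
    it = np.ndindex(ny, nx)
    for (iy, ix) in it:
        if mask is not None and not mask[iy, ix]:
            masked[iy, ix] = True
            continue
        try:
            fit = two_stage_fit(imgs[:, iy, ix], psi_map[iy, ix],
                                r2_map[iy, ix], cfg, consts, te, comp_assumed)
        except np.linalg.LinAlgError:
            masked[iy, ix] = True
            continue
        x_map[:, iy, ix] = fit.x
        phi_map[iy, ix] = fit.phi_rad
        res_map[iy, ix] = fit.residual
        masked[iy, ix] |= fit.masked
        bnd[iy, ix] |= fit.boundary
    if progress:
        logger.info("fit_image: %d voxels fitted", int((~masked).sum()))
    return {
        "x": x_map, "psi": psi_map, "r2star": r2_map, "phi": phi_map,
        "residual": res_map, "masked": masked, "boundary": bnd,
    }


def fac_maps_from_fits(fit_maps: dict, f_trifa: float = 0.0) -> dict:
    """FAC maps (PDFF, ndb, nmidb, SFA, MUFA, PUFA) from fitted amplitudes.

    Applies the subcomponent-to-composition conversion voxelwise; voxels
    with undefined composition (Fntg = 0 or masked) are added to the
    validity mask.  ``f_trifa`` applies the triunsaturated-fat PUFA
    correction where the true oil content is known (phantoms).
    """
    x = fit_maps["x"]
    _, ny, nx = x.shape
    out = {k: np.zeros((ny, nx)) for k in
           ("pdff", "ndb", "nmidb", "sfa", "mufa", "pufa")}
    valid = ~fit_maps["masked"]
    for iy in range(ny):
        for ix in range(nx):
            if not valid[iy, ix]:
                continue
            ndb, nmidb, frac, masked = fac_from_subcomponents(x[:, iy, ix])
            if masked:
                valid[iy, ix] = False
                out["pdff"][iy, ix] = frac.pdff
                continue
            out["pdff"][iy, ix] = frac.pdff
            out["ndb"][iy, ix] = ndb
            out["nmidb"][iy, ix] = nmidb
            out["sfa"][iy, ix] = frac.sfa
            out["mufa"][iy, ix] = frac.mufa
            if f_trifa > 0:
                from .triglyceride_model import pufa_with_trifa_correction
                out["pufa"][iy, ix] = pufa_with_trifa_correction(nmidb, f_trifa)
            else:
                out["pufa"][iy, ix] = frac.pufa
    out["valid"] = valid
    return out
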