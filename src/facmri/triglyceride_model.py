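"""Multi-resonance triglyceride signal model for chemical-shift-encoded MRI.

Triglycerides are modelled with nine distinguishable proton resonances
(labelled A..I, from the terminal methyl at 0.90 ppm to the olefinic
protons at 5.29 ppm).  The relative magnitude of each resonance is a
simple function of three parameters characterising the "mean
triglyceride" of a voxel or an oil:

* ``cl``     -- mean fatty-acid chain length (carbons),
* ``ndb``    -- mean number of double bonds per triglyceride,
* ``nmidb``  -- mean number of methylene-interrupted double bonds.

This module houses the resonance table, the 10x4 component-weight matrix
that splits each resonance magnitude into contributions constant per
triglyceride, proportional to ``ndb`` and proportional to ``nmidb``, the
complex basis matrix used by the variable-projection fit, and the
conversions between fitted fat subcomponents and fatty-acid-composition
(FAC) fractions: saturated (SFA), monounsaturated (MUFA) and
polyunsaturated (PUFA).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

logger = logging.getLogger("facmri")

__all__ = [
    "RESONANCE_LABELS",
    "RESONANCE_TYPES",
    "RESONANCE_SHIFTS_PPM",
    "ResonanceTable",
    "TriglycerideComposition",
    "SpectralConstants",
    "FACFractions",
    "relative_magnitudes",
    "chain_length_heuristic",
    "component_weight_matrix",
    "basis_matrix",
    "fat_frequencies_hz",
    "fac_from_subcomponents",
    "pufa_with_trifa_correction",
    "fit_composition_from_peak_areas",
    "fit_composition_from_csv",
]

# ---------------------------------------------------------------------------
# Resonance table
# ---------------------------------------------------------------------------

RESONANCE_LABELS = ("A", "B", "C", "D", "E", "F", "G", "H", "I")

RESONANCE_TYPES = (
    "methyl",
    "methylene",
    "beta-carboxyl",
    "alpha-olefinic",
    "alpha-carboxyl",
    "diacyl",
    "glycerol",
    "glycerol",
    "olefinic",
)

#: chemical shifts delta_m in ppm, order A..I
RESONANCE_SHIFTS_PPM = (0.90, 1.30, 1.60, 2.02, 2.24, 2.75, 4.20, 5.19, 5.29)


def _magnitude_rules():
    """Per-resonance magnitude rules rho_m(cl, ndb, nmidb)."""
    return (
        lambda cl, ndb, nmidb: 9.0,                                  # A
        lambda cl, ndb, nmidb: (cl - 4.0) * 6.0 - ndb * 8.0 + nmidb * 2.0,  # B
        lambda cl, ndb, nmidb: 6.0,                                  # C
        lambda cl, ndb, nmidb: (ndb - nmidb) * 4.0,                  # D
        lambda cl, ndb, nmidb: 6.0,                                  # E
        lambda cl, ndb, nmidb: nmidb * 2.0,                          # F
        lambda cl, ndb, nmidb: 4.0,                                  # G
        lambda cl, ndb, nmidb: 1.0,                                  # H
        lambda cl, ndb, nmidb: ndb * 2.0,                            # I
    )


@dataclass(frozen=True)
class ResonanceTable:
    """The nine triglyceride proton resonances and their magnitude rules."""

    labels: tuple = RESONANCE_LABELS
    types: tuple = RESONANCE_TYPES
    shifts_ppm: tuple = RESONANCE_SHIFTS_PPM
    magnitude_rules: tuple = field(default_factory=_magnitude_rules)

    def __post_init__(self):
        if not (len(self.labels) == len(self.shifts_ppm) == 9):
            raise ValueError("resonance table must have exactly 9 entries")


DEFAULT_RESONANCE_TABLE = ResonanceTable()


class CompositionError(ValueError):
    """A triglyceride composition violates a physical validity rule."""


@dataclass(frozen=True)
class TriglycerideComposition:
    """Mean-triglyceride parameters (cl, ndb, nmidb) of a voxel or oil.

    Invariants: ``cl > 4`` (the methylene magnitude ``6(cl-4)`` must be
    meaningful), ``ndb >= 0``, ``0 <= nmidb <= ndb`` and every resonance
    magnitude evaluated at the composition must be nonnegative.
    """

    cl: float
    ndb: float
    nmidb: float

    def __post_init__(self):
        if not self.cl > 4.0:
            raise CompositionError(f"chain length must exceed 4, got cl={self.cl}")
        if self.ndb < 0:
            raise CompositionError(f"ndb must be nonnegative, got ndb={self.ndb}")
        if not 0.0 <= self.nmidb <= self.ndb:
            raise CompositionError(
                f"nmidb must lie in [0, ndb], got nmidb={self.nmidb}, ndb={self.ndb}"
            )
        b = (self.cl - 4.0) * 6.0 - self.ndb * 8.0 + self.nmidb * 2.0
        if b < 0:
            raise CompositionError(
                "methylene magnitude 6(cl-4) - 8 ndb + 2 nmidb is negative "
                f"({b:.3f}) for cl={self.cl}, ndb={self.ndb}, nmidb={self.nmidb}"
            )


@dataclass(frozen=True)
class SpectralConstants:
    """Field strength and spectral reference constants.

    ``gamma_hz_per_t`` is the proton gyromagnetic ratio over 2*pi, so fat-water
    frequency offsets come out directly in Hz:
    ``f_m = gamma * B0 * (delta_m - delta_w) * 1e-6``.
    ``delta_w`` (the water shift, ppm) is fixed per run and recorded in
    output metadata; 4.7 ppm is the conventional value at body temperature.
    """

    b0_tesla: float = 3.0
    gamma_hz_per_t: float = 42.577478518e6
    delta_w_ppm: float = 4.7

    def __post_init__(self):
        if self.b0_tesla <= 0:
            raise ValueError("b0_tesla must be positive")


# ---------------------------------------------------------------------------
# Magnitudes and matrices
# ---------------------------------------------------------------------------


def relative_magnitudes(comp: TriglycerideComposition,
                        table: ResonanceTable = DEFAULT_RESONANCE_TABLE) -> np.ndarray:
    """Relative magnitudes rho_A..rho_I of the nine fat resonances."""
    rho = np.array(
        [rule(comp.cl, comp.ndb, comp.nmidb) for rule in table.magnitude_rules],
        dtype=float,
    )
    if np.any(rho < -1e-12):
        bad = RESONANCE_LABELS[int(np.argmin(rho))]
        raise CompositionError(f"negative magnitude for resonance {bad}")
    return rho


def chain_length_heuristic(ndb: float) -> float:
    """Heuristic mean chain length, ``cl = 16.8 + 0.25 ndb``."""
    if ndb < 0:
        raise CompositionError(f"ndb must be nonnegative, got {ndb}")
    return 16.8 + 0.25 * ndb


def component_weight_matrix(comp: TriglycerideComposition) -> np.ndarray:
    """10x4 weight matrix rho: rows (water, A..I), columns (W, Fntg, Fndb, Fnmidb).

    Each fat resonance magnitude is split into a part constant per
    triglyceride, a part proportional to ndb and a part proportional to
    nmidb, so that ``rho @ (0, 1, ndb, nmidb)`` reproduces
    :func:`relative_magnitudes`.
    """
    cl = comp.cl
    return np.array(
        [
            [1.0, 0.0, 0.0, 0.0],          # water
            [0.0, 9.0, 0.0, 0.0],          # A methyl
            [0.0, 6.0 * (cl - 4.0), -8.0, 2.0],  # B methylene
            [0.0, 6.0, 0.0, 0.0],          # C
            [0.0, 0.0, 4.0, -4.0],         # D
            [0.0, 6.0, 0.0, 0.0],          # E
            [0.0, 0.0, 0.0, 2.0],          # F
            [0.0, 4.0, 0.0, 0.0],          # G
            [0.0, 1.0, 0.0, 0.0],          # H
            [0.0, 0.0, 2.0, 0.0],          # I
        ]
    )


def fat_frequencies_hz(consts: SpectralConstants) -> np.ndarray:
    """Fat resonance frequency offsets relative to water, in Hz.

    Computed as ``gamma * B0 * (delta_m - delta_w) * 1e-6``; the methyl
    resonance ends up near -485 Hz at 3 T (about -3.8 ppm below water).
    """
    shifts = np.asarray(RESONANCE_SHIFTS_PPM)
    return consts.gamma_hz_per_t * consts.b0_tesla * (shifts - consts.delta_w_ppm) * 1e-6


def proton_density_scale(comp: TriglycerideComposition) -> float:
    """Scale putting the fat subcomponents in water-proton units.

    The raw component weights count protons per triglyceride, so the raw
    fat amplitudes are ~2 orders of magnitude smaller than a water
    amplitude of equal proton density.  Dividing the fat columns by
    ``s0 = (6 cl + 2 - 2 ndb) / (1 + ndb + nmidb)`` (evaluated at the
    assumed composition) makes ``F = Fntg + Fndb + Fnmidb`` the fat
    proton density on the same scale as W, so that ``PDFF = F/(F+W)``
    is the proton density fat fraction.
    """
    total = 6.0 * comp.cl + 2.0 - 2.0 * comp.ndb
    return total / (1.0 + comp.ndb + comp.nmidb)


def basis_matrix(te: np.ndarray, comp: TriglycerideComposition, r2star: float,
                 consts: SpectralConstants, normalize: str = "proton") -> np.ndarray:
    """N x 4 complex basis A: columns (water, Fntg, Fndb, Fnmidb) time courses.

    Column 1 is the on-resonance water decay ``exp(-R2* t)``; the fat
    columns are the nine resonance phasors ``exp(i 2 pi f_m t)`` weighted by
    the corresponding column of the component-weight matrix, all damped by
    ``exp(-R2* t)``.  With ``normalize='proton'`` (default) the fat
    columns are divided by :func:`proton_density_scale` so the fitted
    amplitudes are commensurate with water and ``F/(F+W)`` is the
    proton-density fat fraction; ``normalize='raw'`` keeps the raw
    proton-count weights.
    """
    te = np.asarray(te, dtype=float)
    if te.ndim != 1 or te.size < 4:
        raise ValueError("need at least 4 echo times for the 4-component model")
    if np.any(np.diff(te) <= 0):
        raise ValueError("echo times must be strictly increasing")
    if r2star < 0:
        raise ValueError("r2star must be nonnegative")

    rho = component_weight_matrix(comp)            # (10, 4)
    freqs = fat_frequencies_hz(consts)             # (9,)
    phasors = np.empty((te.size, 10), dtype=complex)
    phasors[:, 0] = 1.0                            # water on-resonance
    phasors[:, 1:] = np.exp(2j * np.pi * np.outer(te, freqs))
    decay = np.exp(-r2star * te)
    a = (phasors @ rho) * decay[:, None]
    if normalize == "proton":
        a[:, 1:] /= proton_density_scale(comp)
    elif normalize != "raw":
        raise ValueError(f"unknown normalize convention {normalize!r}")
    return a


# ---------------------------------------------------------------------------
# FAC fractions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FACFractions:
    """Fatty-acid-composition fractions of a voxel (unit scale, not %).

    ``sfa + ufa = 1`` and ``ufa = mufa + pufa`` hold for the raw values;
    the ``*`` fields are clamped to [0, 1] for reporting while the raw
    (unclamped) values are retained in ``raw``.
    """

    sfa: float
    mufa: float
    pufa: float
    ufa: float
    pdff: float
    raw: tuple = ()
    clamped: bool = False


def _clamp01(v: float) -> float:
    return min(1.0, max(0.0, v))


def fac_from_subcomponents(x) -> tuple:
    """FAC parameters from a fitted subcomponent vector ``(W, Fntg, Fndb, Fnmidb)``.

    The composition ratios use absolute values of the fat subcomponents,
    ``ndb = |Fndb|/|Fntg|`` and ``nmidb = |Fnmidb|/|Fntg|``; then
    ``UFA = (ndb - nmidb)/3``, ``PUFA = nmidb/3``, ``MUFA = UFA - PUFA``,
    ``SFA = 1 - UFA``.  PDFF uses the signed sum ``F = Fntg+Fndb+Fnmidb``
    in ``F/(F+W)``.  A voxel with ``Fntg = 0`` has undefined composition
    and is flagged as masked rather than raising.

    Returns ``(ndb, nmidb, FACFractions, masked)``.
    """
    w, fntg, fndb, fnmidb = (float(v) for v in x)
    f = fntg + fndb + fnmidb
    denom = f + w
    pdff = f / denom if denom != 0 else 0.0
    if fntg == 0.0:
        return (np.nan, np.nan,
                FACFractions(np.nan, np.nan, np.nan, np.nan, _clamp01(pdff)),
                True)
    ndb = abs(fndb) / abs(fntg)
    nmidb = abs(fnmidb) / abs(fntg)
    ufa = (ndb - nmidb) / 3.0
    pufa = nmidb / 3.0
    mufa = ufa - pufa
    sfa = 1.0 - ufa
    raw = (sfa, mufa, pufa, ufa, pdff)
    clamped_vals = tuple(_clamp01(v) for v in raw)
    clamped = clamped_vals != raw
    if clamped:
        logger.debug("FAC fractions clamped to [0,1]: raw=%s", raw)
    frac = FACFractions(*clamped_vals, raw=raw, clamped=clamped)
    return ndb, nmidb, frac, False


def pufa_with_trifa_correction(nmidb: float, f_trifa: float) -> float:
    """PUFA fraction with correction for triunsaturated fatty acids.

    Plant oils such as flaxseed contain fatty acids with three double
    bonds, which inflate nmidb; for oils of known triunsaturated content
    the PUFA fraction is ``nmidb/3 - f_trifa``, clamped at zero.
    """
    if not 0.0 <= f_trifa <= 1.0:
        raise ValueError("f_trifa must be a fraction in [0, 1]")
    pufa = nmidb / 3.0 - f_trifa
    if pufa < 0:
        logger.debug("PUFA clamped at 0 (nmidb=%g, f_trifa=%g)", nmidb, f_trifa)
        return 0.0
    return pufa


# ---------------------------------------------------------------------------
# Composition from NMR-style peak areas
# ---------------------------------------------------------------------------


def fit_composition_from_peak_areas(areas) -> TriglycerideComposition:
    """Least-squares (cl, ndb, nmidb) from nine measured peak areas.

    Both the measured areas and the model magnitudes are normalised to
    unit sum, removing the arbitrary spectrometer scale.  The bounded
    problem (cl in [10, 24], ndb in [0, 9], nmidb in [0, ndb], enforced by
    optimising the ratio nmidb/ndb) is solved from five deterministic
    starting points to avoid local minima.
    """
    areas = np.asarray(areas, dtype=float)
    if areas.shape != (9,):
        raise ValueError("expected 9 peak areas (resonances A..I)")
    if np.any(areas < 0):
        raise ValueError("peak areas must be nonnegative")
    total = areas.sum()
    if total <= 0:
        raise ValueError("peak areas are all zero")
    target = areas / total

    def model(p):
        cl, ndb, ratio = p
        nmidb = ratio * ndb
        rho = np.array([rule(cl, ndb, nmidb) for rule in _magnitude_rules()])
        s = rho.sum()
        return rho / s if s > 0 else rho

    def resid(p):
        return model(p) - target

    starts = [
        (16.8, 0.5, 0.1),  # near-saturated start
        (17.4, 2.5, 0.26),
        (17.5, 4.0, 0.5),
        (13.0, 0.3, 0.2),
        (18.0, 6.5, 0.6),
    ]
    best = None
    for p0 in starts:
        sol = least_squares(
            resid, p0, bounds=([10.0, 0.0, 0.0], [24.0, 9.0, 1.0]),
            xtol=1e-14, ftol=1e-14, gtol=1e-14,
        )
        if best is None or sol.cost < best.cost:
            best = sol
    cl, ndb, ratio = best.x
    return TriglycerideComposition(cl=cl, ndb=ndb, nmidb=ratio * ndb)


def fit_composition_from_csv(path) -> TriglycerideComposition:
    """Composition fit from a peak-area table (columns ``label``, ``area``).

    Rows are matched to resonances A..I by label; all nine must be
    present exactly once.
    """
    import pandas as pd

    frame = pd.read_csv(path)
    if not {"label", "area"} <= set(frame.columns):
        raise ValueError("peak-area CSV needs 'label' and 'area' columns")
    frame = frame.set_index(frame["label"].astype(str).str.strip().str.upper())
    if sorted(frame.index) != list(RESONANCE_LABELS):
        raise ValueError("peak-area CSV must contain labels A..I exactly once")
    areas = frame.loc[list(RESONANCE_LABELS), "area"].to_numpy(dtype=float)
    return fit_composition_from_peak_areas(areas)
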