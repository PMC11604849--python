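"""Digital phantoms and forward simulation of multi-coil radial k-space.

Two phantom families are provided: an oil-emulsion phantom mirroring a
physical validation phantom (vials of plant oils emulsified in water at
several volume fractions, sitting in a water bath) and simple disc
phantoms for unit tests.  Ground-truth maps — the linear signal
amplitudes (W, Fntg, Fndb, Fnmidb), off-resonance, R2*, initial phase,
and the underlying triglyceride composition — are rasterised onto a
pixel grid and pushed through the voxelwise multi-resonance signal
model; multi-coil radial k-space is then sampled with an exact
non-uniform DFT along golden-angle spokes and complex Gaussian noise is
added.

Conventions
-----------
* Image pixel coordinates are centred: x, y in {-N/2, ..., N/2-1}.
* k-space coordinates are in cycles/FOV, |k| <= N/2.
* The forward transform is ``s(k) = sum_x I(x) exp(-2 pi i k.x / N)``,
  so a spoke sample at k = 0 equals the image sum (mean times N^2).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import h5py
import numpy as np

from .sequence_design import AcquisitionDesign
from .triglyceride_model import (
    SpectralConstants,
    TriglycerideComposition,
    fat_frequencies_hz,
)

__all__ = [
    "OilSpec",
    "Region",
    "PhantomDefinition",
    "RadialKSpace",
    "WATER_PROTONS",
    "WATER_MOLAR_MASS_G_MOL",
    "WATER_DENSITY_G_ML",
    "builtin_oil_library",
    "nominal_pdff_from_volume_fraction",
    "make_oil_phantom",
    "rasterize_phantom",
    "simulate_echo_images",
    "birdcage_coil_maps",
    "radial_trajectory",
    "ndft2_forward",
    "ndft2_adjoint",
    "sample_radial_kspace",
    "write_kspace_h5",
    "read_kspace_h5",
]

# water reference constants for the nominal-PDFF conversion
WATER_PROTONS = 2
WATER_MOLAR_MASS_G_MOL = 18.015
WATER_DENSITY_G_ML = 0.997


# ---------------------------------------------------------------------------
# Oils
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OilSpec:
    """A named oil: mean triglyceride composition plus physical constants.

    ``protons_per_molecule`` defaults to the MR-visible proton count of
    the mean triglyceride, ``6 cl + 2 - 2 ndb`` (the sum of the nine
    resonance magnitudes).
    """

    name: str
    comp: TriglycerideComposition
    f_trifa: float
    density_g_ml: float
    molar_mass_g_mol: float
    protons_per_molecule: float = None

    def __post_init__(self):
        if self.density_g_ml <= 0 or self.molar_mass_g_mol <= 0:
            raise ValueError("density and molar mass must be positive")
        if not 0.0 <= self.f_trifa <= 1.0:
            raise ValueError("f_trifa must be in [0, 1]")
        if self.protons_per_molecule is None:
            n = 6.0 * self.comp.cl + 2.0 - 2.0 * self.comp.ndb
            object.__setattr__(self, "protons_per_molecule", n)


def _oil_from_chain_profile(name, cl, sfa, mufa, pufa2, pufa3,
                            density, molar_mass):
    """Build an OilSpec from per-chain fatty-acid fractions.

    ``sfa/mufa/pufa2/pufa3`` are the fractions of fatty-acid chains with
    0/1/2/3 double bonds.  Per triglyceride (three chains):
    ``ndb = 3 (mufa + 2 pufa2 + 3 pufa3)`` and each 2-double-bond chain
    carries one methylene-interrupted pair, each 3-double-bond chain two,
    so ``nmidb = 3 (pufa2 + 2 pufa3)``.
    """
    total = sfa + mufa + pufa2 + pufa3
    if abs(total - 1.0) > 1e-6:
        raise ValueError(f"{name}: chain fractions sum to {total}, expected 1")
    ndb = 3.0 * (mufa + 2.0 * pufa2 + 3.0 * pufa3)
    nmidb = 3.0 * (pufa2 + 2.0 * pufa3)
    return OilSpec(
        name=name,
        comp=TriglycerideComposition(cl=cl, ndb=ndb, nmidb=nmidb),
        f_trifa=pufa3,
        density_g_ml=density,
        molar_mass_g_mol=molar_mass,
    )


def builtin_oil_library() -> list:
    """Five plant oils plus the two mixtures used in the validation layout.

    Chain-fraction profiles are literature-typical values (USDA food
    composition ranges): fractions of chains with 0/1/2/3 double bonds
    and mean chain length.  They serve as simulation ground truth only.
    Mixtures combine components mole-weighted from their mass fractions.
    """
    coconut = _oil_from_chain_profile(
        "coconut", cl=12.9, sfa=0.92, mufa=0.06, pufa2=0.02, pufa3=0.0,
        density=0.924, molar_mass=660.0)
    olive = _oil_from_chain_profile(
        "olive", cl=17.6, sfa=0.15, mufa=0.73, pufa2=0.11, pufa3=0.01,
        density=0.911, molar_mass=879.0)
    avocado = _oil_from_chain_profile(
        "avocado", cl=17.5, sfa=0.17, mufa=0.66, pufa2=0.16, pufa3=0.01,
        density=0.916, molar_mass=875.0)
    sesame = _oil_from_chain_profile(
        "sesame", cl=17.6, sfa=0.15, mufa=0.40, pufa2=0.44, pufa3=0.01,
        density=0.921, molar_mass=873.0)
    flaxseed = _oil_from_chain_profile(
        "flaxseed", cl=17.8, sfa=0.09, mufa=0.18, pufa2=0.16, pufa3=0.57,
        density=0.930, molar_mass=873.0)
    mix_ca = mix_oils("coconut/avocado 50/50", [(coconut, 0.5), (avocado, 0.5)])
    mix_cs = mix_oils("coconut/sesame 25/75", [(coconut, 0.25), (sesame, 0.75)])
    return [coconut, olive, avocado, sesame, flaxseed, mix_ca, mix_cs]


def mix_oils(name: str, parts) -> OilSpec:
    """Mix oils by mass fraction; composition averaged mole-weighted."""
    masses = np.array([w for _, w in parts], dtype=float)
    moles = masses / np.array([o.molar_mass_g_mol for o, _ in parts])
    mole_frac = moles / moles.sum()
    cl = sum(f * o.comp.cl for (o, _), f in zip(parts, mole_frac))
    ndb = sum(f * o.comp.ndb for (o, _), f in zip(parts, mole_frac))
    nmidb = sum(f * o.comp.nmidb for (o, _), f in zip(parts, mole_frac))
    f_trifa = sum(f * o.f_trifa for (o, _), f in zip(parts, mole_frac))
    volumes = masses / np.array([o.density_g_ml for o, _ in parts])
    density = masses.sum() / volumes.sum()
    molar_mass = masses.sum() / moles.sum()
    return OilSpec(
        name=name,
        comp=TriglycerideComposition(cl=cl, ndb=ndb, nmidb=nmidb),
        f_trifa=f_trifa,
        density_g_ml=density,
        molar_mass_g_mol=molar_mass,
    )


def nominal_pdff_from_volume_fraction(oil: OilSpec, v_frac: float) -> float:
    """Nominal PDFF of an oil-in-water emulsion of given volume fraction.

    Converts the volumetric oil fraction into a proton-density fat
    fraction using the oil's density, molar mass and protons per
    molecule against the water reference constants.
    """
    if not 0.0 <= v_frac <= 1.0:
        raise ValueError("volume fraction must be in [0, 1]")
    oil_h = oil.density_g_ml / oil.molar_mass_g_mol * oil.protons_per_molecule
    water_h = WATER_DENSITY_G_ML / WATER_MOLAR_MASS_G_MOL * WATER_PROTONS
    num = oil_h * v_frac
    den = num + water_h * (1.0 - v_frac)
    return num / den if den > 0 else 0.0


# ---------------------------------------------------------------------------
# Phantom definition and rasterisation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Region:
    """A disc or rectangle filled with an oil emulsion (or pure water)."""

    shape: str                  # "disc" or "rect"
    params: tuple               # disc: (cy, cx, radius); rect: (y0, y1, x0, x1)
    oil: OilSpec = None         # None -> water
    oil_volume_fraction: float = 0.0
    r2star: float = 30.0        # 1/s

    def mask(self, grid) -> np.ndarray:
        ny, nx = grid
        yy, xx = np.mgrid[0:ny, 0:nx]
        if self.shape == "disc":
            cy, cx, r = self.params
            return (yy - cy) ** 2 + (xx - cx) ** 2 <= r ** 2
        if self.shape == "rect":
            y0, y1, x0, x1 = self.params
            return (yy >= y0) & (yy < y1) & (xx >= x0) & (xx < x1)
        raise ValueError(f"unknown region shape {self.shape!r}")


@dataclass(frozen=True)
class PhantomDefinition:
    """Grid, regions and confounder field models of a digital phantom.

    ``field_map_poly`` / ``phase_map_poly`` are coefficient arrays for a
    2-D polynomial in normalised coordinates u, v in [-1, 1]
    (``numpy.polynomial.polynomial.polyval2d``), giving Hz and radians.
    """

    grid: tuple
    regions: tuple
    background_water: bool = True
    bath_margin: int = 0          # air border (pixels) around the water bath
    background_r2star: float = 10.0
    field_map_poly: np.ndarray = field(
        default_factory=lambda: np.array([[20.0, -30.0], [40.0, 25.0]]))
    phase_map_poly: np.ndarray = field(
        default_factory=lambda: np.array([[0.3, 0.4], [-0.5, 0.2]]))


def make_oil_phantom(grid: int = 64, oils=None,
                     volume_fractions=(0.25, 0.5, 0.75, 1.0),
                     vial_radius: float = None,
                     field_scale: float = 1.0) -> PhantomDefinition:
    """Vial-array oil-emulsion phantom on a square grid.

    Lays out one row of vials per oil and one column per emulsion volume
    fraction inside a rectangular water bath, mirroring the physical
    validation phantom (oils at 25/50/75% emulsion and 100% oil).  The
    default field map peaks below ~150 Hz, within one aliasing period of
    the 0.9 ms echo spacing.
    """
    if oils is None:
        oils = builtin_oil_library()[:5]
    n_rows, n_cols = len(oils), len(volume_fractions)
    margin = max(2, grid // 16)          # air border around the bath
    inner = grid - 2 * (margin + 1)
    row_pitch = inner / n_rows
    col_pitch = inner / n_cols
    if vial_radius is None:
        # paper-like geometry: 50 mL tubes are ~6 px radius at the
        # reference 192 matrix / 450 mm FOV; keep vials as large as the
        # layout permits with a 2 px separation margin
        vial_radius = max(2.0, min(6.0, min(row_pitch, col_pitch) / 2 - 2))
    regions = []
    for r, oil in enumerate(oils):
        for c, vf in enumerate(volume_fractions):
            regions.append(Region(
                shape="disc",
                params=(margin + 1 + (r + 0.5) * row_pitch,
                        margin + 1 + (c + 0.5) * col_pitch, vial_radius),
                oil=oil,
                oil_volume_fraction=vf,
                r2star=40.0,
            ))
    return PhantomDefinition(
        grid=(grid, grid),
        regions=tuple(regions),
        bath_margin=max(2, grid // 16),
        field_map_poly=field_scale * np.array([[20.0, -30.0], [40.0, 25.0]]),
    )


def rasterize_phantom(defn: PhantomDefinition) -> dict:
    """Per-voxel ground truth maps for a phantom definition.

    Returns a dict with ``x_true`` (4, ny, nx) amplitudes scaled so that
    ``F/(F+W)`` equals the region's nominal PDFF (total amplitude 1),
    ``psi_true`` (Hz), ``r2star_true`` (1/s), ``phi_true`` (rad),
    ``cl``, ``ndb_true``, ``nmidb_true``, ``f_trifa``, ``pdff_true``,
    ``region_labels`` (int, -1 water/background) and ``object_mask``.
    """
    ny, nx = defn.grid
    x_true = np.zeros((4, ny, nx))
    r2star = np.full((ny, nx), defn.background_r2star)
    labels = np.full((ny, nx), -1, dtype=int)
    cl_map = np.zeros((ny, nx))
    ndb_map = np.zeros((ny, nx))
    nmidb_map = np.zeros((ny, nx))
    trifa_map = np.zeros((ny, nx))
    pdff_map = np.zeros((ny, nx))
    if defn.background_water:
        # finite bath with an air border, as a container sitting in the FOV
        mgn = defn.bath_margin
        bath = np.zeros((ny, nx), dtype=bool)
        bath[mgn:ny - mgn, mgn:nx - mgn] = True
        x_true[0][bath] = 1.0
    claimed = np.zeros((ny, nx), dtype=bool)
    for idx, reg in enumerate(defn.regions):
        m = reg.mask(defn.grid)
        if np.any(claimed & m):
            raise ValueError(f"region {idx} overlaps a previous region")
        claimed |= m
        labels[m] = idx
        r2star[m] = reg.r2star
        if reg.oil is None:
            x_true[0][m] = 1.0
            x_true[1:, m] = 0.0
            continue
        comp = reg.oil.comp
        pdff = nominal_pdff_from_volume_fraction(reg.oil, reg.oil_volume_fraction)
        # proton-density units (see triglyceride_model.proton_density_scale):
        # W + F = 1 everywhere (uniform proton density) and F/(F+W) = pdff
        fntg = pdff / (1.0 + comp.ndb + comp.nmidb)
        x_true[0][m] = 1.0 - pdff
        x_true[1][m] = fntg
        x_true[2][m] = comp.ndb * fntg
        x_true[3][m] = comp.nmidb * fntg
        cl_map[m] = comp.cl
        ndb_map[m] = comp.ndb
        nmidb_map[m] = comp.nmidb
        trifa_map[m] = reg.oil.f_trifa
        pdff_map[m] = pdff
    u = np.linspace(-1.0, 1.0, nx)
    v = np.linspace(-1.0, 1.0, ny)
    vv, uu = np.meshgrid(v, u, indexing="ij")
    psi = np.polynomial.polynomial.polyval2d(vv, uu, defn.field_map_poly)
    phi = np.polynomial.polynomial.polyval2d(vv, uu, defn.phase_map_poly)
    return {
        "x_true": x_true,
        "psi_true": psi,
        "r2star_true": r2star,
        "phi_true": phi,
        "cl": cl_map,
        "ndb_true": ndb_map,
        "nmidb_true": nmidb_map,
        "f_trifa": trifa_map,
        "pdff_true": pdff_map,
        "region_labels": labels,
        "object_mask": x_true.sum(axis=0) > 0,
    }


# ---------------------------------------------------------------------------
# Forward signal model
# ---------------------------------------------------------------------------


def simulate_echo_images(truth: dict, design: AcquisitionDesign,
                         consts: SpectralConstants) -> np.ndarray:
    """Complex echo images [te, y, x] from ground-truth maps.

    Voxelwise evaluation of the signal model
    ``y(t) = (W + sum_m rho_m F-weights e^{i 2 pi f_m t}) e^{i 2 pi psi t}
    e^{i phi} e^{-R2* t}`` using each voxel's composition for the
    resonance weights, in proton-density units (the fat sum is divided
    by the voxel's proton-density scale so amplitudes are commensurate
    with water).  Vectorised by splitting the fat resonance sum into
    its cl-independent parts plus the methylene term ``6 (cl - 4)``.
    """
    te = np.asarray(design.te_list)
    x = truth["x_true"]
    psi = truth["psi_true"]
    r2 = truth["r2star_true"]
    phi = truth["phi_true"]
    cl = truth["cl"]
    freqs = fat_frequencies_hz(consts)          # (9,) A..I
    out = np.empty((te.size, *psi.shape), dtype=complex)
    # cl-independent pieces of the rho columns (see component_weight_matrix)
    ntg_base = np.array([9.0, 0.0, 6.0, 0.0, 6.0, 0.0, 4.0, 1.0, 0.0])
    ndb_col = np.array([0.0, -8.0, 0.0, 4.0, 0.0, 0.0, 0.0, 0.0, 2.0])
    nmidb_col = np.array([0.0, 2.0, 0.0, -4.0, 0.0, 2.0, 0.0, 0.0, 0.0])
    ndb_t, nmidb_t = truth["ndb_true"], truth["nmidb_true"]
    has_fat = x[1] > 0
    scale = np.ones_like(cl)
    scale[has_fat] = ((6.0 * cl[has_fat] + 2.0 - 2.0 * ndb_t[has_fat])
                      / (1.0 + ndb_t[has_fat] + nmidb_t[has_fat]))
    for k, t in enumerate(te):
        ph = np.exp(2j * np.pi * freqs * t)     # (9,)
        b_ntg = ph @ ntg_base + ph[1] * 6.0 * (cl - 4.0)   # per-voxel via cl map
        fat = (x[1] * b_ntg + x[2] * (ph @ ndb_col) + x[3] * (ph @ nmidb_col)) / scale
        out[k] = (x[0] + fat) * np.exp(
            (2j * np.pi * psi - r2) * t) * np.exp(1j * phi)
    return out


def birdcage_coil_maps(n_coils: int, shape: tuple, radius_rel: float = 1.3) -> np.ndarray:
    """Smooth synthetic birdcage-style complex coil sensitivities [coil, y, x].

    Coils sit on a circle of relative radius ``radius_rel`` around the
    FOV; each sensitivity falls off with distance from the coil centre
    and carries a smooth phase, mimicking a receive array.  Maps are
    normalised so the root sum of squares is 1 at the FOV centre.
    """
    ny, nx = shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    yc = (yy - (ny - 1) / 2) / (ny / 2)
    xc = (xx - (nx - 1) / 2) / (nx / 2)
    maps = np.empty((n_coils, ny, nx), dtype=complex)
    for c in range(n_coils):
        ang = 2.0 * np.pi * c / n_coils
        py, px = radius_rel * np.sin(ang), radius_rel * np.cos(ang)
        d2 = (yc - py) ** 2 + (xc - px) ** 2
        mag = 1.0 / (0.3 + d2)
        pha = np.exp(1j * (ang + 0.5 * (xc * np.cos(ang) + yc * np.sin(ang))))
        maps[c] = mag * pha
    centre_rss = np.sqrt(np.sum(np.abs(maps[:, ny // 2, nx // 2]) ** 2))
    return maps / centre_rss


# ---------------------------------------------------------------------------
# Radial sampling (exact non-uniform DFT)
# ---------------------------------------------------------------------------


def radial_trajectory(design: AcquisitionDesign, n_readout: int = None) -> np.ndarray:
    """k-space coordinates [te, spoke, readout, 2] in cycles/FOV.

    Each spoke passes through the k-space centre; readout samples span
    |k| <= N/2 along the spoke direction (cos/sin of the golden-angle
    table in the design).  The default readout is 2x oversampled
    (k-step 1/2), the usual radial convention, which also makes the
    density-compensated adjoint accurate near the k-space centre.
    """
    n = design.matrix_size[0]
    if n_readout is None:
        n_readout = 2 * n
    radii = np.arange(n_readout) - n_readout // 2
    radii = radii * (n / n_readout)             # span |k| <= N/2
    angles = design.spoke_angles                # (spokes, n_te)
    n_spokes, n_te = angles.shape
    traj = np.empty((n_te, n_spokes, n_readout, 2))
    for t in range(n_te):
        th = angles[:, t][:, None]
        traj[t, ..., 0] = radii[None, :] * np.cos(th)   # kx
        traj[t, ..., 1] = radii[None, :] * np.sin(th)   # ky
    return traj


def ndft2_forward(image: np.ndarray, k: np.ndarray) -> np.ndarray:
    """Exact type-2 NDFT: sample image at non-uniform k (…, 2) in cycles/FOV.

    ``s(k) = sum_x I(y,x) exp(-2 pi i (kx*x + ky*y)/N)`` with centred
    pixel coordinates.
    """
    ny, nx = image.shape
    kf = k.reshape(-1, 2)
    xs = np.arange(nx) - nx // 2
    ys = np.arange(ny) - ny // 2
    ex = np.exp(-2j * np.pi * np.outer(kf[:, 0], xs) / nx)      # (S, nx)
    ey = np.exp(-2j * np.pi * np.outer(kf[:, 1], ys) / ny)      # (S, ny)
    t = ex @ np.ascontiguousarray(image.T)                      # (S, ny)
    s = np.sum(ey * t, axis=1)
    return s.reshape(k.shape[:-1])


def ndft2_adjoint(samples: np.ndarray, k: np.ndarray, shape: tuple,
                  weights: np.ndarray = None) -> np.ndarray:
    """Adjoint NDFT with optional sample weights (density compensation)."""
    ny, nx = shape
    kf = k.reshape(-1, 2)
    sf = samples.reshape(-1).astype(complex)
    if weights is not None:
        sf = sf * weights.reshape(-1)
    xs = np.arange(nx) - nx // 2
    ys = np.arange(ny) - ny // 2
    ex = np.exp(2j * np.pi * np.outer(kf[:, 0], xs) / nx)
    ey = np.exp(2j * np.pi * np.outer(kf[:, 1], ys) / ny)
    return (ey * sf[:, None]).T @ ex


@dataclass
class RadialKSpace:
    """Multi-coil multi-echo radial k-space with trajectory metadata."""

    samples: np.ndarray             # [coil, te, spoke, readout] complex
    k_coords: np.ndarray            # [te, spoke, readout, 2] cycles/FOV
    design: AcquisitionDesign
    gradient_delays_us: tuple = (0.0, 0.0)
    noise_sigma: float = 0.0
    seed: int = None
    compression_matrix: np.ndarray = None

    @property
    def n_coils(self) -> int:
        return self.samples.shape[0]


def sample_radial_kspace(images: np.ndarray, design: AcquisitionDesign,
                         coil_maps: np.ndarray, noise_sigma: float,
                         seed: int) -> RadialKSpace:
    """Simulate noisy multi-coil radial k-space from echo images.

    Per-coil images (echo image times sensitivity) are sampled along the
    design's golden-angle spokes with the exact NDFT; i.i.d. complex
    Gaussian noise of standard deviation ``noise_sigma`` per channel
    component is added.  Fully reproducible from ``seed``.
    """
    if coil_maps.shape[1:] != images.shape[1:]:
        raise ValueError("coil maps and images have incompatible shapes")
    traj = radial_trajectory(design)
    n_te, n_spokes, n_ro, _ = traj.shape
    n_coils = coil_maps.shape[0]
    rng = np.random.default_rng(seed)
    samples = np.empty((n_coils, n_te, n_spokes, n_ro), dtype=complex)
    for t in range(n_te):
        for c in range(n_coils):
            samples[c, t] = ndft2_forward(images[t] * coil_maps[c], traj[t])
    if noise_sigma > 0:
        noise = rng.standard_normal(samples.shape) + 1j * rng.standard_normal(samples.shape)
        samples = samples + noise_sigma * noise
    return RadialKSpace(
        samples=samples,
        k_coords=traj,
        design=design,
        noise_sigma=noise_sigma,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# HDF5 container
# ---------------------------------------------------------------------------


def write_kspace_h5(path, ks: RadialKSpace, truth: dict = None,
                    coil_maps: np.ndarray = None,
                    consts: SpectralConstants = None) -> None:
    """Write a RadialKSpace (plus optional ground truth) to HDF5."""
    with h5py.File(path, "w") as f:
        f.create_dataset("kspace", data=ks.samples.astype(np.complex64))
        f.create_dataset("traj", data=ks.k_coords.astype(np.float32))
        f.create_dataset("header", data=ks.design.to_json())
        f.attrs["gradient_delays_us"] = ks.gradient_delays_us
        f.attrs["noise_sigma"] = ks.noise_sigma
        if ks.seed is not None:
            f.attrs["seed"] = ks.seed
        if consts is not None:
            f.attrs["b0_tesla"] = consts.b0_tesla
            f.attrs["delta_w_ppm"] = consts.delta_w_ppm
            f.attrs["gamma_hz_per_t"] = consts.gamma_hz_per_t
        if coil_maps is not None:
            f.create_dataset("coil_maps", data=coil_maps.astype(np.complex64))
        if truth is not None:
            g = f.create_group("truth")
            for key, arr in truth.items():
                g.create_dataset(key, data=np.asarray(arr))


def read_kspace_h5(path) -> tuple:
    """Read (RadialKSpace, truth dict or None, coil_maps or None, SpectralConstants)."""
    with h5py.File(path, "r") as f:
        design = AcquisitionDesign.from_json(
            f["header"][()].decode() if isinstance(f["header"][()], bytes)
            else str(f["header"][()]))
        ks = RadialKSpace(
            samples=f["kspace"][()].astype(complex),
            k_coords=f["traj"][()].astype(float),
            design=design,
            gradient_delays_us=tuple(f.attrs.get("gradient_delays_us", (0.0, 0.0))),
            noise_sigma=float(f.attrs.get("noise_sigma", 0.0)),
            seed=int(f.attrs["seed"]) if "seed" in f.attrs else None,
        )
        truth = None
        if "truth" in f:
            truth = {k: f["truth"][k][()] for k in f["truth"]}
        maps = f["coil_maps"][()].astype(complex) if "coil_maps" in f else None
        consts = SpectralConstants(
            b0_tesla=float(f.attrs.get("b0_tesla", 3.0)),
            gamma_hz_per_t=float(f.attrs.get("gamma_hz_per_t", 42.577478518e6)),
            delta_w_ppm=float(f.attrs.get("delta_w_ppm", 4.7)),
        )
    return ks, truth, maps, consts
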