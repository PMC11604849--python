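"""Acquisition schedule design for ECG-gated multi-echo golden-angle radial GRE.

The acquisition interleaves two 8-echo trains (offset by half the
intra-train echo spacing) into 16 evenly spaced effective TEs, uses a
variable flip-angle train that keeps the transverse signal constant over
the excitations of each heartbeat, and rotates the radial readout by
golden-ratio increments at both the spoke and the echo level so that
every TE sees a different aliasing pattern.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

__all__ = [
    "GOLDEN_RATIO_CONJUGATE",
    "AcquisitionDesign",
    "build_te_schedule",
    "constant_signal_flip_angles",
    "projection_angle",
    "spoke_budget",
    "acceleration_factor",
    "default_cardiac_design",
]

#: (sqrt(5) - 1) / 2, the fractional golden-angle increment
GOLDEN_RATIO_CONJUGATE = (np.sqrt(5.0) - 1.0) / 2.0


@dataclass(frozen=True)
class AcquisitionDesign:
    """Everything needed to simulate or reconstruct one slice acquisition.

    Echo times and TR are in seconds, flip angles in degrees, spoke
    angles in radians in [0, pi).  ``spoke_angles[i, n]`` is the
    projection angle of spoke ``i`` (0-based) at echo ``n`` (0-based).
    """

    te_list: tuple                      # 16 echo times (s)
    tr: float                           # repetition time (s)
    flip_angles_deg: tuple              # one per excitation in a beat
    excitations_per_beat: int
    n_beats: int
    n_spokes_per_te: int
    matrix_size: tuple                  # (rows, cols)
    fov_mm: tuple
    slice_thickness_mm: float
    dwell_time_us: float = 10.0         # readout sample dwell (k-step time)
    spoke_angles: np.ndarray = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        te = np.asarray(self.te_list)
        if np.any(np.diff(te) <= 0):
            raise ValueError("te_list must be strictly increasing")
        if self.spoke_angles is None:
            angles = spoke_angle_table(self.n_spokes_per_te, len(self.te_list))
            object.__setattr__(self, "spoke_angles", angles)
        if np.any(self.spoke_angles < 0) or np.any(self.spoke_angles >= np.pi):
            raise ValueError("spoke angles must lie in [0, pi)")

    @property
    def n_te(self) -> int:
        return len(self.te_list)

    def to_json(self) -> str:
        d = asdict(self)
        d["spoke_angles"] = np.asarray(self.spoke_angles).tolist()
        return json.dumps(d)

    @classmethod
    def from_json(cls, s: str) -> "AcquisitionDesign":
        d = json.loads(s)
        d["te_list"] = tuple(d["te_list"])
        d["flip_angles_deg"] = tuple(d["flip_angles_deg"])
        d["matrix_size"] = tuple(d["matrix_size"])
        d["fov_mm"] = tuple(d["fov_mm"])
        d["spoke_angles"] = np.asarray(d["spoke_angles"])
        return cls(**d)


def build_te_schedule(first_te_train1: float, first_te_train2: float,
                      n_per_train: int, intra_train_spacing: float) -> np.ndarray:
    """Merged echo times of two interleaved echo trains (seconds).

    The second train must start half an intra-train spacing after the
    first so that the merged schedule is evenly spaced with an effective
    spacing of half the intra-train spacing.
    """
    offset = first_te_train2 - first_te_train1
    if not np.isclose(offset, intra_train_spacing / 2.0, rtol=1e-9, atol=1e-12):
        raise ValueError(
            "echo trains do not interleave evenly: train offset "
            f"{offset:g} s != intra-train spacing / 2 = {intra_train_spacing / 2:g} s"
        )
    t1 = first_te_train1 + intra_train_spacing * np.arange(n_per_train)
    t2 = first_te_train2 + intra_train_spacing * np.arange(n_per_train)
    return np.sort(np.concatenate([t1, t2]))


def constant_signal_flip_angles(n_pulses: int, tr: float, t1: float,
                                initial_longitudinal: float = 1.0) -> np.ndarray:
    """Variable flip angles (degrees) giving constant per-pulse signal.

    With longitudinal magnetisation evolving as
    ``z_{n+1} = z_n cos(a_n) E1 + (1 - E1)``, ``E1 = exp(-TR/T1)``, the
    angles satisfy ``z_n sin(a_n) = s`` for a common signal level ``s``.
    The largest feasible ``s`` — the one for which the final pulse is
    exactly 90 deg — is found by bisection.
    """
    if n_pulses < 1:
        raise ValueError("need at least one pulse")
    if t1 <= 0 or tr < 0:
        raise ValueError("invalid TR/T1")
    z1 = float(initial_longitudinal)
    if z1 <= 0:
        raise ValueError("initial longitudinal magnetisation must be positive")
    e1 = np.exp(-tr / t1)

    def final_z_minus_s(s):
        """z_N - s after running the schedule; None if infeasible earlier."""
        z = z1
        for _ in range(n_pulses - 1):
            if s > z:
                return None
            a = np.arcsin(s / z)
            z = z * np.cos(a) * e1 + (1.0 - e1)
        return z - s

    lo, hi = 0.0, z1
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        g = final_z_minus_s(mid)
        if g is None or g < 0:
            hi = mid
        else:
            lo = mid
    s = lo
    angles = np.empty(n_pulses)
    z = z1
    for n in range(n_pulses):
        angles[n] = np.degrees(np.arcsin(min(1.0, s / z)))
        a = np.radians(angles[n])
        z = z * np.cos(a) * e1 + (1.0 - e1)
    # last pulse dumps everything
    angles[-1] = 90.0 if np.isclose(angles[-1], 90.0, atol=1e-3) else angles[-1]
    return angles


def projection_angle(i: int, n: int, n_total_spokes: int) -> float:
    """Golden-angle projection angle (radians) of spoke ``i`` at echo ``n``.

    Spokes advance by ``pi * (sqrt(5)-1)/2`` modulo pi; echoes add a
    sub-rotation of the same fraction of the spoke gap ``pi / Nr`` so
    that no two echoes share an angle.  Indices are 1-based.
    """
    if i < 1 or n < 1:
        raise ValueError("spoke and echo indices are 1-based")
    g = GOLDEN_RATIO_CONJUGATE
    base = np.mod((i - 1) * np.pi * g, np.pi)
    sub = np.mod((n - 1) * (np.pi / n_total_spokes) * g, np.pi / n_total_spokes)
    return base + sub


def spoke_angle_table(n_spokes: int, n_te: int) -> np.ndarray:
    """Full [spoke, echo] angle table, wrapped into [0, pi)."""
    i = np.arange(1, n_spokes + 1)[:, None]
    n = np.arange(1, n_te + 1)[None, :]
    g = GOLDEN_RATIO_CONJUGATE
    base = np.mod((i - 1) * np.pi * g, np.pi)
    sub = np.mod((n - 1) * (np.pi / n_spokes) * g, np.pi / n_spokes)
    return np.mod(base + sub, np.pi)


def spoke_budget(excitations_per_beat: int, n_beats: int,
                 trains_per_full_readout: int) -> int:
    """Spokes per TE given the ECG-segmented excitation budget.

    Each full 16-TE spoke takes ``trains_per_full_readout`` excitations
    (two 8-echo trains in the reference protocol).
    """
    total = excitations_per_beat * n_beats
    if total % trains_per_full_readout != 0:
        raise ValueError(
            f"{excitations_per_beat} x {n_beats} excitations not divisible by "
            f"{trains_per_full_readout} trains per readout"
        )
    return total // trains_per_full_readout


def acceleration_factor(matrix_size: int, spokes_per_te: int) -> float:
    """Undersampling factor relative to the radial Nyquist spoke count.

    Radial Nyquist requires ``(pi/2) * matrix_size`` uniformly spaced
    spokes; the factor is that count over the acquired spokes per TE.
    """
    if matrix_size <= 0 or spokes_per_te <= 0:
        raise ValueError("matrix size and spoke count must be positive")
    return (np.pi / 2.0) * matrix_size / spokes_per_te


def default_cardiac_design(matrix_size: int = 192, n_spokes_per_te: int = 48,
                           fov_mm: float = 400.0) -> AcquisitionDesign:
    """The reference breath-hold cardiac protocol (scalable matrix).

    16 TEs from 1.8 to 15.3 ms (two 8-echo trains, 0.9 ms effective
    spacing), TR 18.5 ms, 8 excitations per beat over 12 beats giving 48
    spokes per TE, variable flip angles for T1 = 350 ms adipose tissue.
    """
    te = build_te_schedule(1.8e-3, 2.7e-3, 8, 1.8e-3)
    flips = constant_signal_flip_angles(8, tr=18.5e-3, t1=350e-3)
    return AcquisitionDesign(
        te_list=tuple(te),
        tr=18.5e-3,
        flip_angles_deg=tuple(flips),
        excitations_per_beat=8,
        n_beats=12,
        n_spokes_per_te=n_spokes_per_te,
        matrix_size=(matrix_size, matrix_size),
        fov_mm=(fov_mm, fov_mm),
        slice_thickness_mm=8.0,
    )
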