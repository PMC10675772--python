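"""Ground-truth dynamic-balance computations.

Given force-plate and motion data for one gait cycle, this module computes
the quantities used throughout the package:

* gait events (heel-strike, toe-off of both limbs) from vertical ground
  reaction forces;
* the centre of pressure (COP) from plate forces and moments, and the body
  centre of mass (COM) as the mass-weighted sum of segmental COMs;
* sagittal and frontal inclination angles (IA) of the COM-COP vector with
  respect to the vertical;
* the rate of change of IA (RCIA) by differentiating a GCV-selected
  smoothing spline;
* normalization of any signal to the 101-point (0-100 %) gait cycle.

Sign conventions: sagittal IA is positive when the COM is anterior to the
COP; frontal IA is positive when the COM deviates from the COP towards the
contralateral (swing-side) limb.  The lab frame is right-handed with
``Y = Z x X`` pointing to the walker's left.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline, make_smoothing_spline

__all__ = [
    "GaitEvents",
    "Frame",
    "BalanceCurves",
    "detect_events",
    "compute_cop",
    "combine_cop",
    "compute_com",
    "compute_ia",
    "differentiate_gcv",
    "normalize_cycle",
]

N_CYCLE = 101  # samples of the normalized gait cycle, 0..100 %


@dataclass(frozen=True)
class GaitEvents:
    """Timing anchors of one gait cycle.

    ``hs``..``next_hs`` are sample indices at the rate of the signal the
    events were detected on; the ``*_pct`` attributes express the interior
    events as percent of the HS -> next-HS cycle.
    """

    hs: int
    cto: int
    chs: int
    to: int
    next_hs: int
    rate_hz: float

    def __post_init__(self) -> None:
        if not (self.hs < self.cto < self.chs < self.to < self.next_hs):
            raise ValueError(
                "event ordering violated: need hs < cto < chs < to < next_hs, "
                f"got {(self.hs, self.cto, self.chs, self.to, self.next_hs)}"
            )
        if self.rate_hz <= 0:
            raise ValueError("rate_hz must be positive")

    @property
    def cycle_duration_s(self) -> float:
        return (self.next_hs - self.hs) / self.rate_hz

    def _pct(self, sample: float) -> float:
        return 100.0 * (sample - self.hs) / (self.next_hs - self.hs)

    @property
    def cto_pct(self) -> float:
        return self._pct(self.cto)

    @property
    def chs_pct(self) -> float:
        return self._pct(self.chs)

    @property
    def to_pct(self) -> float:
        return self._pct(self.to)

    @classmethod
    def from_pct(
        cls, cto_pct: float, chs_pct: float, to_pct: float,
        cycle_duration_s: float, rate_hz: float = 100.0,
    ) -> "GaitEvents":
        """Build events from percent-of-cycle anchors (synthetic cohorts)."""
        n = cycle_duration_s * rate_hz
        return cls(
            hs=0,
            cto=int(round(cto_pct / 100.0 * n)),
            chs=int(round(chs_pct / 100.0 * n)),
            to=int(round(to_pct / 100.0 * n)),
            next_hs=int(round(n)),
            rate_hz=rate_hz,
        )


@dataclass(frozen=True)
class Frame:
    """Lab reference frame: progression axis X, vertical axis Z, stance side."""

    progression: np.ndarray = field(
        default_factory=lambda: np.array([1.0, 0.0, 0.0]))
    vertical: np.ndarray = field(
        default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    stance_side: str = "right"

    def __post_init__(self) -> None:
        x = np.asarray(self.progression, float)
        z = np.asarray(self.vertical, float)
        if abs(np.linalg.norm(x) - 1) > 1e-9 or abs(np.linalg.norm(z) - 1) > 1e-9:
            raise ValueError("frame axes must be unit vectors")
        if abs(float(x @ z)) > 1e-9:
            raise ValueError("frame axes must be orthogonal")
        if self.stance_side not in ("left", "right"):
            raise ValueError("stance_side must be 'left' or 'right'")
        object.__setattr__(self, "progression", x)
        object.__setattr__(self, "vertical", z)


@dataclass
class BalanceCurves:
    """Sagittal/frontal IA (deg) and RCIA (deg/s) over the 101-point cycle."""

    sagittal_ia: np.ndarray
    frontal_ia: np.ndarray
    sagittal_rcia: np.ndarray
    frontal_rcia: np.ndarray

    def __post_init__(self) -> None:
        for name in ("sagittal_ia", "frontal_ia", "sagittal_rcia", "frontal_rcia"):
            arr = np.asarray(getattr(self, name), float)
            if arr.shape != (N_CYCLE,):
                raise ValueError(f"{name} must have exactly {N_CYCLE} samples")
            setattr(self, name, arr)
        if np.abs(self.sagittal_ia).max() > 90 or np.abs(self.frontal_ia).max() > 90:
            raise ValueError("inclination angles must lie within +/-90 deg")

    @property
    def ia(self) -> np.ndarray:
        """2 x 101 array, rows = (sagittal, frontal)."""
        return np.vstack([self.sagittal_ia, self.frontal_ia])

    @property
    def rcia(self) -> np.ndarray:
        return np.vstack([self.sagittal_rcia, self.frontal_rcia])


# ---------------------------------------------------------------------------
# gait events
# ---------------------------------------------------------------------------

def _contact_intervals(fz: np.ndarray, threshold: float, debounce: int) -> list[tuple[int, int | None]]:
    """(rise, fall) sample pairs where fz stays above threshold.

    A crossing only counts if the signal stays on the new side for at least
    ``debounce`` samples (open-ended intervals get fall=None).
    """
    above = np.asarray(fz, float) > threshold
    intervals: list[tuple[int, int | None]] = []
    state = bool(above[0])
    start = 0 if state else None
    i = 1
    n = len(above)
    while i < n:
        if above[i] != state:
            run_end = min(n, i + debounce)
            if np.all(above[i:run_end] == above[i]) and run_end - i >= min(debounce, n - i):
                if state:  # falling edge
                    intervals.append((start if start is not None else 0, i))
                    start = None
                else:      # rising edge
                    start = i
                state = bool(above[i])
        i += 1
    if state:
        intervals.append((start if start is not None else 0, None))
    return intervals


def detect_events(
    grf_vertical: np.ndarray,
    rate_hz: float,
    threshold_n: float = 20.0,
    debounce_samples: int = 5,
) -> GaitEvents:
    """Detect HS/CTO/CHS/TO/next-HS from per-plate vertical GRF.

    Parameters
    ----------
    grf_vertical : (n_plates, n_samples) array
        Vertical force of each plate (N); one limb per plate.
    rate_hz : float
        Sampling rate of the force signals.
    threshold_n : float
        Contact threshold: heel-strike is the first sample rising above it,
        toe-off the first sample falling below, with a short debounce to
        reject chatter.

    The ipsilateral plate is identified by the event pattern of one full
    cycle: a strike on plate A while plate B is loaded, B unloading (CTO),
    B striking again (CHS), A unloading (TO), then A striking again.
    """
    grf = np.atleast_2d(np.asarray(grf_vertical, float))
    if grf.shape[0] < 2:
        raise ValueError("need vertical GRF from at least two plates")
    per_plate = [_contact_intervals(fz, threshold_n, debounce_samples) for fz in grf]
    if all(len(iv) == 0 for iv in per_plate):
        raise ValueError("no contact detected")

    for a in range(grf.shape[0]):
        for b in range(grf.shape[0]):
            if a == b:
                continue
            rises_a = [r for r, _ in per_plate[a] if r > 0]
            for hs in rises_a:
                # contralateral plate loaded at hs, unloading after
                cto = next((f for r, f in per_plate[b]
                            if r <= hs and f is not None and f > hs), None)
                if cto is None:
                    continue
                chs = next((r for r, _ in per_plate[b] if r > cto), None)
                if chs is None:
                    continue
                to = next((f for r, f in per_plate[a]
                           if r == hs and f is not None and f > chs), None)
                if to is None:
                    continue
                next_hs = next((r for r, _ in per_plate[a] if r > to), None)
                if next_hs is None:
                    continue
                return GaitEvents(hs=hs, cto=cto, chs=chs, to=to,
                                  next_hs=next_hs, rate_hz=rate_hz)
    raise ValueError("event ordering violated: no consistent HS/CTO/CHS/TO/HS "
                     "pattern found in the plate contacts")


# ---------------------------------------------------------------------------
# COP / COM
# ---------------------------------------------------------------------------

def compute_cop(
    forces: np.ndarray,
    moments: np.ndarray,
    plate_origin: np.ndarray = (0.0, 0.0, 0.0),
    surface_offset_z: float = 0.0,
    fz_threshold: float = 20.0,
) -> np.ma.MaskedArray:
    """Centre of pressure of one plate from forces (N) and moments (N m).

    Standard force-plate formulae with the moment referred to the plate
    origin and the contact surface a height ``surface_offset_z`` above it::

        COP_x = -(M_y + F_x * z0) / F_z + origin_x
        COP_y =  (M_x - F_y * z0) / F_z + origin_y

    Samples with ``F_z`` at or below ``fz_threshold`` are masked rather than
    silently divided.
    Returns an ``(n, 3)`` masked array on the contact surface.
    """
    F = np.asarray(forces, float)
    M = np.asarray(moments, float)
    if F.shape != M.shape or F.ndim != 2 or F.shape[1] != 3:
        raise ValueError("forces and moments must both be (n, 3)")
    origin = np.asarray(plate_origin, float)
    fz = F[:, 2]
    bad = fz <= fz_threshold
    safe_fz = np.where(bad, 1.0, fz)
    cop = np.empty_like(F)
    cop[:, 0] = -(M[:, 1] + F[:, 0] * surface_offset_z) / safe_fz + origin[0]
    cop[:, 1] = (M[:, 0] - F[:, 1] * surface_offset_z) / safe_fz + origin[1]
    cop[:, 2] = origin[2] + surface_offset_z
    mask = np.repeat(bad[:, None], 3, axis=1)
    return np.ma.MaskedArray(cop, mask=mask)


def combine_cop(cops: list[np.ma.MaskedArray], vertical_forces: np.ndarray) -> np.ma.MaskedArray:
    """Net COP of several plates: vertical-force-weighted average.

    Samples where no plate is loaded stay masked.
    """
    fz = np.asarray(vertical_forces, float)  # (n_plates, n)
    if fz.ndim != 2 or len(cops) != fz.shape[0]:
        raise ValueError("need one vertical-force row per plate COP")
    num = np.zeros((fz.shape[1], 3))
    den = np.zeros(fz.shape[1])
    for cop, f in zip(cops, fz):
        w = np.where(np.any(cop.mask, axis=1), 0.0, np.clip(f, 0.0, None))
        num += np.asarray(cop.filled(0.0)) * w[:, None]
        den += w
    bad = den <= 0
    out = num / np.where(bad, 1.0, den)[:, None]
    return np.ma.MaskedArray(out, mask=np.repeat(bad[:, None], 3, axis=1))


def compute_com(segment_coms: np.ndarray, mass_fractions: np.ndarray) -> np.ndarray:
    """Whole-body COM as the mass-weighted sum of segmental COM trajectories.

    ``segment_coms`` is ``(n_segments, n_samples, 3)``; ``mass_fractions``
    must sum to 1 within 1e-6.
    """
    P = np.asarray(segment_coms, float)
    m = np.asarray(mass_fractions, float)
    if P.ndim != 3 or P.shape[2] != 3:
        raise ValueError("segment_coms must be (n_segments, n_samples, 3)")
    if m.shape != (P.shape[0],):
        raise ValueError("one mass fraction per segment required")
    if abs(m.sum() - 1.0) > 1e-6:
        raise ValueError(f"mass fractions must sum to 1, got {m.sum():.8f}")
    return np.einsum("s,stx->tx", m, P)


# ---------------------------------------------------------------------------
# inclination angles
# ---------------------------------------------------------------------------

def compute_ia(
    com: np.ndarray,
    cop: np.ndarray,
    frame: Frame | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Sagittal and frontal inclination angles (deg) of the COM-COP vector.

    With unit vector ``p`` along COP->COM, ``v = Z x p``; the sagittal IA is
    ``asin(v . Y)`` (positive COM anterior to COP) and the frontal IA is
    ``-asin(v . X)`` for right stance / ``+asin(v . X)`` for left stance
    (positive when the COM deviates towards the contralateral limb).
    """
    frame = frame or Frame()
    com = np.asarray(com, float)
    cop = np.asarray(np.ma.getdata(cop), float)
    if com.shape != cop.shape:
        raise ValueError("com and cop must have the same shape")
    P = com - cop
    norm = np.linalg.norm(P, axis=-1)
    if np.any(norm <= 0):
        raise ValueError("COM-COP vector has zero length at some sample")
    p = P / norm[..., None]
    Z = frame.vertical
    X = frame.progression
    Y = np.cross(Z, X)  # leftward for X forward, Z up
    v = np.cross(Z, p)
    v_y = v @ Y
    v_x = v @ X
    over = max(np.abs(v_y).max(), np.abs(v_x).max()) - 1.0
    if over > 1e-12:
        warnings.warn(f"asin argument exceeded 1 by {over:.3e}; clamped",
                      RuntimeWarning, stacklevel=2)
    v_y = np.clip(v_y, -1.0, 1.0)
    v_x = np.clip(v_x, -1.0, 1.0)
    sagittal = np.degrees(np.arcsin(v_y))
    sign = -1.0 if frame.stance_side == "right" else 1.0
    frontal = sign * np.degrees(np.arcsin(v_x))
    return sagittal, frontal


# ---------------------------------------------------------------------------
# differentiation / normalization
# ---------------------------------------------------------------------------

def differentiate_gcv(curve: np.ndarray, times_s: np.ndarray) -> np.ndarray:
    """First derivative via a GCV-selected cubic smoothing spline.

    The smoothing parameter is chosen by generalized cross-validation and
    the analytic derivative of the fitted spline is evaluated at the input
    times.  Needs at least 10 strictly increasing samples.
    """
    y = np.asarray(curve, float)
    t = np.asarray(times_s, float)
    if y.shape != t.shape or y.ndim != 1:
        raise ValueError("curve and times must be equal-length 1-D arrays")
    if len(y) < 10:
        raise ValueError("need at least 10 samples for GCV spline differentiation")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    spline = make_smoothing_spline(t, y, lam=None)
    return spline.derivative()(t)


def smooth_gcv(curve: np.ndarray, times_s: np.ndarray) -> np.ndarray:
    """The GCV smoothing spline itself, evaluated at the input times."""
    y = np.asarray(curve, float)
    t = np.asarray(times_s, float)
    if len(y) < 10:
        raise ValueError("need at least 10 samples")
    return make_smoothing_spline(t, y, lam=None)(t)


def normalize_cycle(
    curve: np.ndarray,
    events: GaitEvents,
    kind: str = "cubic",
) -> np.ndarray:
    """Resample the HS -> next-HS span of ``curve`` onto the 0..100 % grid.

    ``curve`` is indexed at the rate the events refer to.  Interpolation is
    piecewise-cubic for kinematic signals ("cubic") or linear ("linear").
    Already-normalized 101-point inputs spanning exactly one cycle pass
    through unchanged up to interpolation round-off.
    """
    y = np.asarray(curve, float)
    if events.hs < 0 or events.next_hs > len(y) - 1:
        raise ValueError("gait events fall outside the signal")
    idx = np.arange(events.hs, events.next_hs + 1, dtype=float)
    pct_native = 100.0 * (idx - events.hs) / (events.next_hs - events.hs)
    seg = y[events.hs:events.next_hs + 1]
    grid = np.linspace(0.0, 100.0, N_CYCLE)
    if kind == "cubic":
        return CubicSpline(pct_native, seg)(grid)
    if kind == "linear":
        return np.interp(grid, pct_native, seg)
    raise ValueError("kind must be 'cubic' or 'linear'")
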