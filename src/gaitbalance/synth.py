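"""Synthetic gait cohorts with controllable between-group balance effects.

The generator emulates the study design the rest of the package assumes:
two groups (healthy older and young adults), >= 20 gait cycles per subject,
ground-truth sagittal/frontal COM-COP inclination-angle (IA) curves and
their rates of change (RCIA), six waist-IMU channels that are a fixed
smooth invertible mixture of the balance curves (so the IMU -> IA mapping
is learnable by construction), and group differences injected on chosen
balance variables at requested Cohen's d.

Curve model
-----------
Every curve is a finite harmonic series of the gait cycle.  The base
template per plane is the minimum-bending-energy periodic curve
constrained to physiological event values and sub-phase means (sagittal
IA ~ +/-8-10 deg, frontal IA ~ +/-5 deg).  Subject- and trial-level
variability adds random low-order harmonics with fixed amplitudes and
uniform phases.

Effect injection
----------------
A requested effect (variable number, Cohen's d, direction) adds to the
older group a fixed offset curve per plane: the minimum-bending-energy
harmonic whose response on each targeted functional is exactly
``direction * d * sigma_v`` (``sigma_v`` = between-subject SD of the
variable, estimated by a fixed-seed Monte Carlo of the variability model)
while the remaining same-plane functionals are held at their base values —
event values exactly, sub-phase means and ranges as strongly weighted soft
constraints, with range rows relinearized iteratively at the current
window extrema and evaluated as expected ranges under the subject
perturbation distribution.  This keeps the group difference concentrated
on the requested variables instead of leaking into neighbouring event,
mean, or range variables.

``matched_groups=True`` draws identical subject-level perturbations in
both groups (a matched-cohort design), which pins null between-group
differences at ~0 while keeping full between-subject SDs; with the default
``False`` the groups are sampled independently and null variables show
false positives at the nominal alpha rate, as in any real cohort.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from . import clinstat
from .balance import BalanceCurves, GaitEvents, N_CYCLE
from .imuprep import NormalizedTrial, prepare_trial

__all__ = ["CohortSpec", "Cohort", "RawTrial", "SubjectParams",
           "make_cohort", "make_raw_trial"]

_TWO_PI = 2.0 * np.pi

# sampling rates of the emulated laboratory set-up
GRF_RATE = 1200.0
MARKER_RATE = 200.0
IMU_RATE = 100.0

DEFAULT_EFFECTS = ((10, 1.58, -1), (14, 1.39, -1), (20, 0.93, -1))


# ---------------------------------------------------------------------------
# harmonic machinery
# ---------------------------------------------------------------------------

def _design(pct, K: int, deriv: int = 0) -> np.ndarray:
    """Design matrix of [1, cos(k th), sin(k th)]_{k<=K}, th = 2 pi pct/100.

    ``deriv`` differentiates with respect to pct.
    """
    pct = np.atleast_1d(np.asarray(pct, float))
    th = _TWO_PI * pct / 100.0
    cols = [np.ones_like(th) if deriv == 0 else np.zeros_like(th)]
    for k in range(1, K + 1):
        w = k * _TWO_PI / 100.0
        c, s = np.cos(k * th), np.sin(k * th)
        if deriv == 0:
            cols += [c, s]
        elif deriv == 1:
            cols += [-w * s, w * c]
        else:
            raise ValueError("deriv must be 0 or 1")
    return np.stack(cols, axis=-1)


def _bending_diag(K: int) -> np.ndarray:
    q = [1e-8]
    for k in range(1, K + 1):
        w = (k * _TWO_PI / 100.0) ** 2
        q += [50.0 * w * w + 1e-8] * 2  # integral of cos^2 over one cycle = 50
    return np.array(q)


def _min_bending_solve(K: int, C: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Coefficients minimizing the bending energy of the periodic curve
    subject to linear constraints C a = b."""
    q = _bending_diag(K)
    Ci = C / q
    # constraint rows may be linearly dependent (window extrema can coincide
    # with event grid points); the dependencies are consistent, so the
    # min-norm pseudo-inverse solution is the right generalization
    mu = np.linalg.lstsq(Ci @ C.T, b, rcond=1e-10)[0]
    return Ci.T @ mu


def _soft_constrained_solve(
    K: int,
    C_hard: np.ndarray,
    b_hard: np.ndarray,
    C_soft: np.ndarray,
    b_soft: np.ndarray,
    soft_weights: np.ndarray,
) -> np.ndarray:
    """Minimize bending energy + weighted soft-constraint violation subject
    to the hard constraints.

    Soft rows are satisfied when geometrically possible; when a soft
    functional is structurally coupled to a hard one (a window extreme
    sitting on a constrained event, or the discrete rate-mean identity) its
    violation saturates at the minimum the hard constraints force.
    """
    q = _bending_diag(K)
    norms = np.linalg.norm(C_soft, axis=1)
    norms = np.where(norms > 0, norms, 1.0)
    Cs = C_soft / norms[:, None]
    bs = b_soft / norms
    W = np.asarray(soft_weights, float)
    Q = np.diag(q) + (Cs * W[:, None]).T @ Cs
    rhs = (Cs * W[:, None]).T @ bs
    # eliminate the (possibly rank-deficient) hard rows: a = a0 + N y with
    # a0 the min-norm particular solution and N an orthonormal nullspace
    # basis, then solve the reduced quadratic in y
    a0, _, rank, _ = np.linalg.lstsq(C_hard, b_hard, rcond=1e-10)
    _, _, vt = np.linalg.svd(C_hard)
    N = vt[rank:].T
    if N.shape[1] == 0:
        return a0
    y = np.linalg.solve(N.T @ Q @ N, N.T @ (rhs - Q @ a0))
    return a0 + N @ y




_PCT_GRID = np.linspace(0.0, 100.0, N_CYCLE)

# Base template constraints: event values and sub-phase means per plane,
# at the physiological scale of healthy-adult COM-COP inclination angles.
_BASE_K = 10
_SAG_EVENT_VALUES = (7.79, -7.08, 6.30, -7.43)     # HS, CTO, CHS, TO (deg)
_FRO_EVENT_VALUES = (4.63, -3.46, -4.07, 3.53)
_SAG_PHASE_MEANS = (-0.57, 0.11, -0.33, -0.02)     # iDLS, SLS, tDLS, SW
_FRO_PHASE_MEANS = (0.49, -3.78, -0.45, 3.73)
# early-single-support dip of the frontal RCIA (deg/s at the nominal cycle
# duration): keeps the contralateral-toe-off value off the window extremes,
# as in measured curves where the deepest frontal rate lies inside stance
_FRO_RCIA_DIP = (20.0, -60.0)

# Subject-level harmonic perturbation amplitudes (deg) for k = 1, 2, 3;
# trial-level jitter reuses them scaled by TRIAL_JITTER.
_SAG_PERT_AMPL = (0.9, 0.7, 0.5)
_FRO_PERT_AMPL = (0.6, 0.5, 0.3)
_PERT_K = 3
TRIAL_JITTER = 0.3

_INJECT_K = 12
_SIGMA_MC_SEED = 987654321
_SIGMA_MC_SUBJECTS = 1200


@dataclass(frozen=True)
class CohortSpec:
    """Study-design parameters of a synthetic cohort."""

    n_old: int = 13
    n_young: int = 13
    trials_per_subject: int = 20
    cycle_duration_mean_s: float = 1.1
    cycle_duration_sd_s: float = 0.1
    event_pcts: tuple[float, float, float] = (12.0, 50.0, 62.0)  # CTO, CHS, TO
    effect_spec: tuple[tuple[int, float, int], ...] = DEFAULT_EFFECTS
    noise_sd_accel: float = 0.1     # m/s^2 on each accelerometer channel
    noise_sd_gyro: float = 1.0      # deg/s on each gyroscope channel
    matched_groups: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_old < 2 or self.n_young < 2:
            raise ValueError("need at least two subjects per group")
        if self.trials_per_subject < 1:
            raise ValueError("trials_per_subject must be >= 1")
        cto, chs, to = self.event_pcts
        if not (0 < cto < chs < to < 100):
            raise ValueError("event percents must satisfy 0 < CTO < CHS < TO < 100")
        if min(self.cycle_duration_mean_s, self.cycle_duration_sd_s + 1e-12) <= 0:
            raise ValueError("cycle duration parameters must be positive")
        if self.noise_sd_accel < 0 or self.noise_sd_gyro < 0:
            raise ValueError("noise SDs must be non-negative")
        for var, d, direction in self.effect_spec:
            if not (1 <= int(var) <= 48):
                raise ValueError(f"effect on non-existent variable number {var}")
            if d < 0:
                raise ValueError("target Cohen's d must be non-negative")
            if direction not in (-1, 1):
                raise ValueError("effect direction must be -1 or +1")


@dataclass
class SubjectParams:
    """Per-subject generative parameters (used by make_raw_trial)."""

    cycle_duration_s: float = 1.1
    event_pcts: tuple[float, float, float] = (12.0, 50.0, 62.0)
    stance_side: str = "right"
    sag_coefs: np.ndarray | None = None   # harmonic coefficients; None = base
    fro_coefs: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.cycle_duration_s <= 0:
            raise ValueError("cycle duration must be positive")


@dataclass
class RawTrial:
    """Laboratory-rate signals of one synthetic trial.

    ``forces``/``moments`` are (2 plates, n, 3) at 1200 Hz (plate 0 is the
    ipsilateral limb); ``com`` is (n, 3) at 200 Hz; ``imu`` is (6, n) at
    100 Hz.  ``events`` index the 1200 Hz signals.  ``ia_template`` holds
    the generating 2 x 101 IA curves for round-trip checks.
    """

    forces: np.ndarray
    moments: np.ndarray
    com: np.ndarray
    segment_coms: np.ndarray
    mass_fractions: np.ndarray
    imu: np.ndarray
    imu_events: GaitEvents
    events: GaitEvents
    stance_side: str
    cycle_duration_s: float
    ia_template: np.ndarray
    rcia_template: np.ndarray


@dataclass
class Cohort:
    """A generated cohort: normalized trials plus ground-truth statistics."""

    spec: CohortSpec
    trials: list[NormalizedTrial]
    variable_table: clinstat.VariableTable

    def subjects(self) -> list[str]:
        return list(self.variable_table.values.index)


# ---------------------------------------------------------------------------
# template construction
# ---------------------------------------------------------------------------

def _event_indices(event_pcts) -> np.ndarray:
    cto, chs, to = event_pcts
    return np.array([0, round(cto), round(chs), round(to)], dtype=int)


def _window_slices(event_pcts) -> list[slice]:
    cto, chs, to = (round(p) for p in event_pcts)
    return [slice(0, cto + 1), slice(cto, chs + 1),
            slice(chs, to + 1), slice(to, 101)]


def base_coefficients(event_pcts=(12.0, 50.0, 62.0)) -> tuple[np.ndarray, np.ndarray]:
    """Base-template harmonic coefficients (sagittal, frontal), K = 8."""
    ev = np.array([0.0, *event_pcts])
    B0 = _design(_PCT_GRID, _BASE_K)
    rows_ev = _design(ev, _BASE_K)
    slices = _window_slices(event_pcts)
    rows_mean = np.array([B0[s].mean(axis=0) for s in slices])
    C = np.vstack([rows_ev, rows_mean])
    a_sag = _min_bending_solve(_BASE_K, C, np.array(
        [*_SAG_EVENT_VALUES, *_SAG_PHASE_MEANS]))
    dip_pct, dip_value = _FRO_RCIA_DIP
    row_dip = _design(np.array([dip_pct]), _BASE_K, deriv=1) * (100.0 / 1.1)
    a_fro = _min_bending_solve(_BASE_K, np.vstack([C, row_dip]), np.array(
        [*_FRO_EVENT_VALUES, *_FRO_PHASE_MEANS, dip_value]))
    return a_sag, a_fro


def _pad(a: np.ndarray, K: int) -> np.ndarray:
    out = np.zeros(1 + 2 * K)
    out[:len(a)] = a
    return out


def _plane_rows_and_values(
    cur_ia: np.ndarray,
    cur_rcia: np.ndarray,
    K: int,
    event_pcts,
    cycle_s: float,
) -> tuple[np.ndarray, np.ndarray]:
    """The 24 plane functionals linearized at the curve (cur_ia, cur_rcia).

    Returns ``(C, vals)``: ``C`` are the functional rows on the harmonic
    basis (ranges linearized at the current within-window argmax/argmin),
    ``vals`` the functional values of the current curve itself.  Row order:
    IA events (HS, CTO, CHS, TO), RCIA events, IA means, RCIA means,
    IA ranges, RCIA ranges.  RCIA rows are in deg/s at ``cycle_s``.
    """
    idx = _event_indices(event_pcts)
    slices = _window_slices(event_pcts)
    B0 = _design(_PCT_GRID, K)
    B1 = _design(_PCT_GRID, K, deriv=1) * (100.0 / cycle_s)
    rows, vals = [], []
    for grid, B in ((cur_ia, B0), (cur_rcia, B1)):
        for i in idx:
            rows.append(B[i]); vals.append(grid[i])
    for grid, B in ((cur_ia, B0), (cur_rcia, B1)):
        for s in slices:
            rows.append(B[s].mean(axis=0)); vals.append(grid[s].mean())
    for grid, B in ((cur_ia, B0), (cur_rcia, B1)):
        for s in slices:
            seg = grid[s]
            rows.append(B[s][seg.argmax()] - B[s][seg.argmin()])
            vals.append(seg.max() - seg.min())
    return np.array(rows), np.array(vals)


def _expected_range_rows(
    cur_ia: np.ndarray,
    cur_rcia: np.ndarray,
    K: int,
    event_pcts,
    cycle_s: float,
    eps_ia: np.ndarray,
    eps_rcia: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Expected-range functional rows and values under curve perturbations.

    For each sub-phase window, the range of ``cur + eps`` is averaged over
    the perturbation draws; the gradient row weights each grid point by the
    frequency with which it is the window argmax/argmin.  Aligning the
    compensation with the expectation removes the bias that noise-free
    range preservation leaves behind (a perturbed subject's extremes sit
    wherever the injection wiggles push them).
    """
    slices = _window_slices(event_pcts)
    B0 = _design(_PCT_GRID, K)
    B1 = _design(_PCT_GRID, K, deriv=1) * (100.0 / cycle_s)
    rows, vals = [], []
    for grid, eps, B in ((cur_ia, eps_ia, B0), (cur_rcia, eps_rcia, B1)):
        for s in slices:
            seg = grid[s] + eps[:, s]               # (M, window)
            amax = seg.argmax(axis=1)
            amin = seg.argmin(axis=1)
            w = np.bincount(amax, minlength=seg.shape[1]).astype(float)
            w -= np.bincount(amin, minlength=seg.shape[1])
            w /= seg.shape[0]
            rows.append(w @ B[s])
            vals.append(float(np.mean(seg.max(axis=1) - seg.min(axis=1))))
    return np.array(rows), np.array(vals)


def _variable_plane_and_row(var: int) -> tuple[str, int]:
    """Map a variable number to (plane, row index within the 24 plane rows)."""
    info = clinstat.VARIABLE_INFO.loc[var]
    kind = {"event": 0, "mean": 1, "range": 2}[info.kind]
    quantity = 0 if info.quantity == "IA" else 1
    anchors = clinstat.EVENTS if info.kind == "event" else clinstat.SUBPHASES
    a = anchors.index(info.anchor)
    # plane rows: [IA_event, RCIA_event, IA_mean, RCIA_mean, IA_range, RCIA_range]
    return info.plane, (2 * kind + quantity) * 4 + a


def group_difference_curve(
    a_base: np.ndarray,
    targets: dict[int, float],
    event_pcts=(12.0, 50.0, 62.0),
    cycle_s: float = 1.1,
    n_iter: int = 12,
    eps_draws: tuple[np.ndarray, np.ndarray] | None = None,
) -> np.ndarray:
    """Smooth offset curve realizing requested functional shifts of a plane.

    ``targets`` maps plane-row indices (see ``_plane_rows_and_values``) to
    the desired additive shift; the remaining functionals of
    ``base + offset`` are held at their base values.  Because a range
    functional moves its own argmax/argmin, the system is solved by
    iterative relinearization: each pass re-locates the window extrema of
    the current curve and compensates there, so e.g. lowering the RCIA at
    contralateral toe-off does not drag the surrounding sub-phase ranges
    with it.  Returns coefficients on the K = 12 harmonic basis.
    """
    a_base = np.asarray(a_base, float)
    Kb = (len(a_base) - 1) // 2
    base_ia = _design(_PCT_GRID, Kb) @ a_base
    base_rcia = (_design(_PCT_GRID, Kb, deriv=1) @ a_base) * (100.0 / cycle_s)
    _, desired = _plane_rows_and_values(base_ia, base_rcia, _INJECT_K,
                                        event_pcts, cycle_s)
    if eps_draws is not None:
        _, desired[16:24] = _expected_range_rows(
            base_ia, base_rcia, _INJECT_K, event_pcts, cycle_s, *eps_draws)
    for row, delta in targets.items():
        desired[row] += delta
    # event and targeted rows are enforced exactly.  Mean rows are soft
    # with a high weight: a discrete identity ties the four window means of
    # the rate grid to its event values, so exact preservation of all means
    # under a rate-event shift is impossible (the tiny violation spreads
    # over the windows).  Range rows are soft with a lower weight and
    # relinearized each pass at the current window extrema.
    hard = sorted(set(range(8)) | set(targets))
    soft = [r for r in range(8, 24) if r not in targets]
    weights = np.array([1e3 if r < 16 else 1e2 for r in soft])
    B0 = _design(_PCT_GRID, _INJECT_K)
    B1 = _design(_PCT_GRID, _INJECT_K, deriv=1) * (100.0 / cycle_s)
    a = np.zeros(1 + 2 * _INJECT_K)
    for _ in range(n_iter):
        cur_ia = base_ia + B0 @ a
        cur_rcia = base_rcia + B1 @ a
        C, vals = _plane_rows_and_values(cur_ia, cur_rcia, _INJECT_K,
                                         event_pcts, cycle_s)
        if eps_draws is not None:
            C[16:24], vals[16:24] = _expected_range_rows(
                cur_ia, cur_rcia, _INJECT_K, event_pcts, cycle_s, *eps_draws)
        resid = desired - vals
        step = _soft_constrained_solve(_INJECT_K, C[hard], resid[hard],
                                       C[soft], resid[soft], weights)
        a = a + step
        if np.abs(step).max() < 1e-10:
            break
    return a


def injection_curves(
    spec: "CohortSpec",
    sigma: np.ndarray,
) -> dict[str, np.ndarray]:
    """Per-plane old-group offset coefficients realizing the spec's effects.

    Amplitude of each effect is ``direction * d * sigma[var]``; effects on
    the same plane are solved jointly so their range compensations interact
    correctly.
    """
    a_sag, a_fro = base_coefficients(spec.event_pcts)
    base = {"sagittal": a_sag, "frontal": a_fro}
    per_plane: dict[str, dict[int, float]] = {}
    for var, d, direction in spec.effect_spec:
        plane, row = _variable_plane_and_row(var)
        per_plane.setdefault(plane, {})[row] = direction * d * sigma[var - 1]
    # fixed-seed perturbation draws so the range compensation targets the
    # expected ranges under subject-level variability (common random numbers
    # for base and injected curves)
    rng = np.random.default_rng(_SIGMA_MC_SEED + 1)
    amp = {"sagittal": np.repeat(_SAG_PERT_AMPL, 2),
           "frontal": np.repeat(_FRO_PERT_AMPL, 2)}
    Bp0 = _design(_PCT_GRID, _PERT_K)[:, 1:]
    Bp1 = _design(_PCT_GRID, _PERT_K, deriv=1)[:, 1:]
    out = {}
    for plane, targets in per_plane.items():
        Z = rng.standard_normal((400, 2 * _PERT_K)) * amp[plane]
        eps = (Z @ Bp0.T, (Z @ Bp1.T) * (100.0 / spec.cycle_duration_mean_s))
        out[plane] = group_difference_curve(
            base[plane], targets, spec.event_pcts,
            spec.cycle_duration_mean_s, eps_draws=eps)
    return out


# ---------------------------------------------------------------------------
# vectorized variable extraction (internal, mirrors clinstat.extract_variables)
# ---------------------------------------------------------------------------

def _extract_many(sag_ia, fro_ia, sag_rc, fro_rc, event_pcts) -> np.ndarray:
    """(M, 48) variables from (M, 101) curve stacks."""
    idx = _event_indices(event_pcts)
    slices = _window_slices(event_pcts)
    curves = (sag_ia, fro_ia, sag_rc, fro_rc)
    cols = []
    for y in curves:
        cols.extend(y[:, i] for i in idx)
    for y in curves:
        cols.extend(y[:, s].mean(axis=1) for s in slices)
    for y in curves:
        cols.extend(y[:, s].max(axis=1) - y[:, s].min(axis=1) for s in slices)
    return np.column_stack(cols)


def subject_variability_sd(spec: CohortSpec) -> np.ndarray:
    """Between-subject SD of each of the 48 variables under the spec's
    variability model (no injected effects), by fixed-seed Monte Carlo.

    Includes subject-level harmonic perturbations, cycle-duration spread,
    and averaging over the spec's number of trials with trial-level jitter.
    """
    rng = np.random.default_rng(_SIGMA_MC_SEED)
    M = _SIGMA_MC_SUBJECTS
    ntr = min(spec.trials_per_subject, 8)  # averaging saturates quickly
    a_sag, a_fro = base_coefficients(spec.event_pcts)
    B0 = _design(_PCT_GRID, _PERT_K)[:, 1:]
    B1 = _design(_PCT_GRID, _PERT_K, deriv=1)[:, 1:]
    base = {
        "sag": (_design(_PCT_GRID, _BASE_K) @ a_sag,
                _design(_PCT_GRID, _BASE_K, deriv=1) @ a_sag),
        "fro": (_design(_PCT_GRID, _BASE_K) @ a_fro,
                _design(_PCT_GRID, _BASE_K, deriv=1) @ a_fro),
    }
    amp = {"sag": np.repeat(_SAG_PERT_AMPL, 2), "fro": np.repeat(_FRO_PERT_AMPL, 2)}
    T_subj = np.clip(rng.normal(spec.cycle_duration_mean_s,
                                spec.cycle_duration_sd_s, M), 0.6, None)
    T_subj = np.round(T_subj, 2)
    z = {plane: rng.standard_normal((M, 2 * _PERT_K)) * amp[plane]
         for plane in ("sag", "fro")}
    vals = np.zeros((M, 48))
    for _ in range(ntr):
        T = np.clip(np.round(T_subj + rng.normal(0.0, 0.02, M), 2), 0.6, None)
        grids = {}
        for plane in ("sag", "fro"):
            zt = (z[plane] + rng.standard_normal((M, 2 * _PERT_K))
                  * amp[plane] * TRIAL_JITTER)
            grids[plane + "_ia"] = base[plane][0] + zt @ B0.T
            grids[plane + "_rc"] = ((base[plane][1] + zt @ B1.T)
                                    * (100.0 / T)[:, None])
        vals += _extract_many(grids["sag_ia"], grids["fro_ia"],
                              grids["sag_rc"], grids["fro_rc"], spec.event_pcts)
    vals /= ntr
    return vals.std(axis=0, ddof=1)


# ---------------------------------------------------------------------------
# IMU synthesis
# ---------------------------------------------------------------------------

# fixed full-rank mixing of the six latent gait signals into IMU channels
_MIXING = np.array([
    [0.9, -0.3, 0.2, -0.1, 0.5, 0.2],
    [-0.2, 0.8, -0.1, 0.3, -0.4, 0.6],
    [0.3, 0.4, 0.6, -0.2, 0.3, -0.5],
    [-0.5, 0.2, 0.7, 0.6, -0.1, 0.3],
    [0.1, -0.6, -0.3, 0.8, 0.2, 0.4],
    [0.4, 0.1, -0.4, 0.2, 0.9, -0.3],
])
_CHANNEL_SCALE = np.array([2.0, 2.0, 2.0, 30.0, 30.0, 30.0])
_CHANNEL_OFFSET = np.array([0.3, -0.2, 9.81, 0.0, 0.0, 0.0])
# typical magnitudes used to normalize the latents before mixing
_LATENT_SCALE = np.array([8.0, 5.0, 120.0, 80.0, 1.0, 1.0])


def _imu_channels(pct, a_sag, a_fro, K, cycle_s, rng, spec) -> np.ndarray:
    """Six IMU channels at the given (possibly fractional) pct positions."""
    pct = np.mod(pct, 100.0)
    B0 = _design(pct, K)
    B1 = _design(pct, K, deriv=1)
    th = _TWO_PI * pct / 100.0
    lat = np.stack([
        B0 @ a_sag,
        B0 @ a_fro,
        (B1 @ a_sag) * (100.0 / cycle_s),
        (B1 @ a_fro) * (100.0 / cycle_s),
        np.sin(th + 0.7),
        np.cos(2.0 * th - 0.4),
    ]) / _LATENT_SCALE[:, None]
    mixed = _MIXING @ lat
    chans = _CHANNEL_SCALE[:, None] * (mixed + 0.3 * np.tanh(mixed))
    chans += _CHANNEL_OFFSET[:, None]
    noise_sd = np.array([spec.noise_sd_accel] * 3 + [spec.noise_sd_gyro] * 3)
    chans += rng.standard_normal(chans.shape) * noise_sd[:, None]
    return chans


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

def _subject_draw(rng, spec) -> dict:
    amp_s = np.repeat(_SAG_PERT_AMPL, 2)
    amp_f = np.repeat(_FRO_PERT_AMPL, 2)
    T = float(np.clip(rng.normal(spec.cycle_duration_mean_s,
                                 spec.cycle_duration_sd_s), 0.6, None))
    return {
        "z_sag": rng.standard_normal(2 * _PERT_K) * amp_s,
        "z_fro": rng.standard_normal(2 * _PERT_K) * amp_f,
        "T": round(T, 2),
    }


def make_cohort(spec: CohortSpec) -> Cohort:
    """Generate a full cohort of normalized trials plus ground truth.

    Identical spec (including seed) gives a bit-identical cohort.
    """
    rng = np.random.default_rng(spec.seed)
    K = max(_BASE_K, _PERT_K, _INJECT_K)
    a_sag, a_fro = base_coefficients(spec.event_pcts)
    a_sag, a_fro = _pad(a_sag, K), _pad(a_fro, K)

    # old-group offset curves realizing the requested effect sizes
    deltas: dict[str, np.ndarray] = {}
    if spec.effect_spec:
        sigma = subject_variability_sd(spec)
        deltas = {plane: _pad(coefs, K)
                  for plane, coefs in injection_curves(spec, sigma).items()}

    B0 = _design(_PCT_GRID, K)
    B1 = _design(_PCT_GRID, K, deriv=1)
    amp = {"sag": np.repeat(_SAG_PERT_AMPL, 2),
           "fro": np.repeat(_FRO_PERT_AMPL, 2)}

    trials: list[NormalizedTrial] = []
    per_subject: dict[str, tuple[str, list]] = {}
    group_sizes = (("old", spec.n_old), ("young", spec.n_young))

    # matched design: pre-draw shared subject-level parameters
    shared = None
    if spec.matched_groups:
        n_shared = max(spec.n_old, spec.n_young)
        shared = [_subject_draw(rng, spec) for _ in range(n_shared)]

    for group, n in group_sizes:
        for j in range(n):
            sub = shared[j] if spec.matched_groups else _subject_draw(rng, spec)
            sid = f"{group}{j + 1:02d}"
            subject_trials = []
            for k in range(spec.trials_per_subject):
                T = float(np.clip(round(
                    sub["T"] + rng.normal(0.0, 0.02), 2), 0.6, None))
                z_sag = sub["z_sag"] + rng.standard_normal(
                    2 * _PERT_K) * amp["sag"] * TRIAL_JITTER
                z_fro = sub["z_fro"] + rng.standard_normal(
                    2 * _PERT_K) * amp["fro"] * TRIAL_JITTER
                csag, cfro = a_sag.copy(), a_fro.copy()
                csag[1:1 + 2 * _PERT_K] += z_sag
                cfro[1:1 + 2 * _PERT_K] += z_fro
                if group == "old":
                    if "sagittal" in deltas:
                        csag = csag + deltas["sagittal"]
                    if "frontal" in deltas:
                        cfro = cfro + deltas["frontal"]
                sag_ia = B0 @ csag
                fro_ia = B0 @ cfro
                sag_rc = (B1 @ csag) * (100.0 / T)
                fro_rc = (B1 @ cfro) * (100.0 / T)
                events = GaitEvents.from_pct(*spec.event_pcts,
                                             cycle_duration_s=T,
                                             rate_hz=IMU_RATE)
                curves = BalanceCurves(sag_ia, fro_ia, sag_rc, fro_rc)

                # native-rate IMU with margins so filtering edges stay
                # outside the cycle
                n_pre = int(round(0.15 * T * IMU_RATE))
                n_tot = int(round(T * IMU_RATE)) + 2 * n_pre + 1
                t = (np.arange(n_tot) - n_pre) / IMU_RATE
                imu_raw = _imu_channels(100.0 * t / T, csag, cfro, K, T,
                                        rng, spec)
                imu_events = GaitEvents(
                    hs=n_pre, cto=n_pre + events.cto, chs=n_pre + events.chs,
                    to=n_pre + events.to, next_hs=n_pre + events.next_hs,
                    rate_hz=IMU_RATE)
                trial = prepare_trial(
                    imu_raw, imu_events, curves.ia, curves.rcia,
                    rate_hz=IMU_RATE, subject_id=sid, group=group,
                    trial_id=f"{sid}_t{k + 1:03d}")
                trials.append(trial)
                subject_trials.append((curves, events))
            per_subject[sid] = (group, subject_trials)

    table = clinstat.VariableTable.from_subject_curves(per_subject)
    return Cohort(spec=spec, trials=trials, variable_table=table)


# ---------------------------------------------------------------------------
# raw laboratory-rate trial
# ---------------------------------------------------------------------------

# 13-segment mass fractions (head, upper trunk, lower trunk, L/R upper arm,
# L/R forearm+hand, L/R thigh, L/R shank, L/R foot)
MASS_FRACTIONS = np.array([0.081, 0.216, 0.281, 0.028, 0.028, 0.022, 0.022,
                           0.100, 0.100, 0.0465, 0.0465, 0.0145, 0.0145])

_STANCE_SHAPE_M = 0.3  # second-harmonic admixture of the M-shaped GRF bump


def _stance_profile(s: np.ndarray) -> np.ndarray:
    """Symmetric double-bump vertical-GRF shape on stance fraction s in [0,1]."""
    return np.sin(np.pi * s) + _STANCE_SHAPE_M * np.sin(3 * np.pi * s)


def _stance_force(t, t_on, t_off, peak_n, threshold_n):
    """Vertical force crossing ``threshold_n`` exactly at t_on and t_off."""
    frac = threshold_n / peak_n
    s_c = brentq(lambda s: _stance_profile(np.array([s]))[0] - frac, 0.0, 0.25)
    L = (t_off - t_on) / (1.0 - 2.0 * s_c)
    s = (t - (t_on - s_c * L)) / L
    out = np.zeros_like(t)
    inside = (s > 0) & (s < 1)
    out[inside] = peak_n * _stance_profile(s[inside])
    return out


def make_raw_trial(subject_params: SubjectParams, seed: int = 0) -> RawTrial:
    """Generate one trial's laboratory-rate signals.

    Force plates cross the 20 N contact threshold at the encoded events
    (within one 1200 Hz sample), the COM/COP trajectories reproduce the
    subject's IA template by construction, and the IMU channels follow the
    fixed latent mixing.  The window spans 20 % of a cycle before HS to
    25 % after the next HS so every event is observable.
    """
    sp = subject_params
    T = sp.cycle_duration_s
    cto_pct, chs_pct, to_pct = sp.event_pcts
    rng = np.random.default_rng(seed)
    K = max(_BASE_K, _INJECT_K)
    a_sag, a_fro = base_coefficients(sp.event_pcts)
    a_sag = _pad(a_sag, K) if sp.sag_coefs is None else _pad(sp.sag_coefs, K)
    a_fro = _pad(a_fro, K) if sp.fro_coefs is None else _pad(sp.fro_coefs, K)

    t0, t1 = -0.20 * T, 1.25 * T
    n_grf = int(round((t1 - t0) * GRF_RATE)) + 1
    t_grf = t0 + np.arange(n_grf) / GRF_RATE
    threshold, peak = 20.0, 700.0

    # plate 0: ipsilateral limb (HS at t = 0, TO at to_pct, next HS at T)
    fz0 = (_stance_force(t_grf, 0.0, to_pct / 100.0 * T, peak, threshold)
           + _stance_force(t_grf, T, T + to_pct / 100.0 * T, peak, threshold))
    # plate 1: contralateral limb (loaded at window start, CTO, CHS ...)
    fz1 = (_stance_force(t_grf, -(1.0 - cto_pct / 100.0) * T,
                         cto_pct / 100.0 * T, peak, threshold)
           + _stance_force(t_grf, chs_pct / 100.0 * T,
                           (1.0 + cto_pct / 100.0) * T, peak, threshold))

    # overall COP path on the floor; both plates share it during double
    # support so the force-weighted net COP equals the template path
    speed = 1.25 / T  # m/s progression
    cop_x = speed * t_grf
    cop_y = 0.04 * np.sin(_TWO_PI * t_grf / T)
    cop = np.column_stack([cop_x, cop_y, np.zeros_like(t_grf)])

    forces = np.zeros((2, n_grf, 3))
    moments = np.zeros((2, n_grf, 3))
    for p, fz in enumerate((fz0, fz1)):
        forces[p, :, 2] = fz
        forces[p, :, 0] = 0.12 * fz * np.sin(_TWO_PI * t_grf / T)
        forces[p, :, 1] = 0.05 * fz * np.cos(_TWO_PI * t_grf / T)
        moments[p, :, 0] = cop[:, 1] * fz
        moments[p, :, 1] = -cop[:, 0] * fz
    events = GaitEvents(
        hs=int(round(-t0 * GRF_RATE)),
        cto=int(round((-t0 + cto_pct / 100.0 * T) * GRF_RATE)),
        chs=int(round((-t0 + chs_pct / 100.0 * T) * GRF_RATE)),
        to=int(round((-t0 + to_pct / 100.0 * T) * GRF_RATE)),
        next_hs=int(round((-t0 + T) * GRF_RATE)),
        rate_hz=GRF_RATE)

    # COM: COP path plus the COM-COP unit vector encoded by the IA template
    n_mk = int(round((t1 - t0) * MARKER_RATE)) + 1
    t_mk = t0 + np.arange(n_mk) / MARKER_RATE
    pct = np.mod(100.0 * t_mk / T, 100.0)
    sag = np.radians(_design(pct, K) @ a_sag)
    fro = np.radians(_design(pct, K) @ a_fro)
    sign = 1.0 if sp.stance_side == "right" else -1.0
    p_x = np.sin(sag)
    p_y = sign * np.sin(fro)
    p_z = np.sqrt(1.0 - p_x ** 2 - p_y ** 2)
    com_height = 0.95
    cop_mk = np.column_stack([speed * t_mk,
                              0.04 * np.sin(_TWO_PI * t_mk / T),
                              np.zeros_like(t_mk)])
    com = cop_mk + com_height * np.column_stack([p_x, p_y, p_z])

    # rigid constellation of 13 segment COMs whose weighted mean is the COM
    offsets = rng.normal(0.0, 0.25, (13, 3))
    offsets -= MASS_FRACTIONS @ offsets
    segment_coms = com[None, :, :] + offsets[:, None, :]

    n_imu = int(round((t1 - t0) * IMU_RATE)) + 1
    t_imu = t0 + np.arange(n_imu) / IMU_RATE
    spec = CohortSpec()
    imu = _imu_channels(100.0 * t_imu / T, a_sag, a_fro, K, T, rng, spec)
    imu_events = GaitEvents(
        hs=int(round(-t0 * IMU_RATE)),
        cto=int(round((-t0 + cto_pct / 100.0 * T) * IMU_RATE)),
        chs=int(round((-t0 + chs_pct / 100.0 * T) * IMU_RATE)),
        to=int(round((-t0 + to_pct / 100.0 * T) * IMU_RATE)),
        next_hs=int(round((-t0 + T) * IMU_RATE)),
        rate_hz=IMU_RATE)

    B0g = _design(_PCT_GRID, K)
    B1g = _design(_PCT_GRID, K, deriv=1)
    ia_template = np.vstack([B0g @ a_sag, B0g @ a_fro])
    rcia_template = np.vstack([(B1g @ a_sag) * (100.0 / T),
                               (B1g @ a_fro) * (100.0 / T)])
    return RawTrial(
        forces=forces, moments=moments, com=com,
        segment_coms=segment_coms, mass_fractions=MASS_FRACTIONS.copy(),
        imu=imu, imu_events=imu_events, events=events,
        stance_side=sp.stance_side, cycle_duration_s=T,
        ia_template=ia_template, rcia_template=rcia_template)
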