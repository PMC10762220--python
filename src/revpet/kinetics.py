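"""Reference-tissue kinetic modeling: baseline MRTM and lp-ntPET.

Baseline model (multilinear reference-tissue operational equation):

    C_T(t) = R1 C_R(t) + k2 int_0^t C_R - k2a int_0^t C_T

with k2 = R1 * k2' when the reference-region clearance k2' is fixed
(estimated once from a large whole-striatum region), and baseline
BP_ND = k2/k2a - 1. The linear parametric neurotransmitter PET
(lp-ntPET) extension adds a time-varying efflux term for transient
dopamine release,

    ... - gamma int_0^t B(s) C_T(s) ds,

where B is one of a small set of unit-peak gamma-variate basis
functions locked to the reward-reversal onset. Fits are linear weighted
least squares per basis; the basis minimising the residual sum of
squares wins, and the release fit is compared to baseline through an
extra-sum-of-squares F statistic, thresholded (default F > 9.55) to
mask voxels with credible displacement.

All running integrals are trapezoidal on frame midpoints anchored at
(t=0, C=0); rate constants are reported per minute.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .tac import TAC, FrameSchedule, GammaResponse

__all__ = [
    "KineticFit",
    "OccupancyCurve",
    "VoxelwiseResult",
    "SingularFitError",
    "mrtm_baseline_fit",
    "build_reversal_basis",
    "lp_ntpet_fit",
    "f_statistic",
    "occupancy_curve",
    "predicted_path",
    "temporal_smooth",
    "voxelwise_fit",
]

F_MASK_DEFAULT = 9.55
DEFAULT_PEAK_OFFSETS_MIN = (1.0, 2.0, 4.0, 8.0, 12.0)


class SingularFitError(ValueError):
    """Raised when the kinetic design matrix is rank-deficient."""


@dataclass(frozen=True)
class KineticFit:
    """Parameter estimates for one TAC under baseline or lp-ntPET."""

    r1: float
    k2_per_min: float
    k2a_per_min: float
    k2_prime_per_min: float
    bp_nd_baseline: float
    gamma_per_min: float
    basis: GammaResponse | None
    basis_index: int | None
    rss: float
    f_stat: float | None
    gamma_clamped: bool
    fitted: np.ndarray
    target: TAC
    reference: TAC
    weights: np.ndarray

    @property
    def is_release_model(self) -> bool:
        return self.basis is not None

    def dynamic_bp(self, t_s: np.ndarray | float) -> np.ndarray:
        """Time-resolved BP_ND(t) = k2 / (k2a + gamma*B(t)) - 1."""
        t = np.asarray(t_s, dtype=float)
        k2a_t = self.k2a_per_min + (
            self.gamma_per_min * self.basis.value(t) if self.basis is not None else 0.0
        )
        return self.k2_per_min / k2a_t - 1.0


@dataclass(frozen=True)
class OccupancyCurve:
    """Time-resolved receptor occupancy derived from a kinetic fit:
    Occupancy(%) = (pre BP_ND - BP_ND(t)) / pre BP_ND * 100."""

    times_s: np.ndarray
    occupancy_pct: np.ndarray
    peak_occupancy_pct: float
    peak_time_s: float
    pre_bp: float
    post_bp: float


@dataclass(frozen=True)
class VoxelwiseResult:
    """Voxelwise lp-ntPET fits with F masking and a two-step ROI refit."""

    f_map: np.ndarray
    gamma_map: np.ndarray
    mask: np.ndarray
    roi_fit: KineticFit | None
    f_threshold: float

    @property
    def n_masked(self) -> int:
        return int(self.mask.sum())


def _running_integral_min(times_s: np.ndarray, values: np.ndarray) -> np.ndarray:
    """Cumulative trapezoid over frame midpoints, anchored at (0, 0),
    in activity * minutes."""
    t = np.concatenate([[0.0], times_s]) / 60.0
    v = np.concatenate([[0.0], values])
    return np.cumsum(np.diff(t) * 0.5 * (v[1:] + v[:-1]))


def _frame_weights(fs: FrameSchedule, weights: str | np.ndarray) -> np.ndarray:
    if isinstance(weights, str):
        if weights == "frame_duration":
            w = fs.durations_s / fs.durations_s.mean()
        elif weights == "uniform":
            w = np.ones(fs.n_frames)
        else:
            raise ValueError(f"unknown weighting scheme {weights!r}")
        return w
    w = np.asarray(weights, dtype=float)
    if w.shape != (fs.n_frames,) or (w <= 0).any():
        raise ValueError("weights must be positive, one per frame")
    return w


def _wlstsq(design: np.ndarray, y: np.ndarray, w: np.ndarray) -> tuple[np.ndarray, float]:
    sw = np.sqrt(w)
    a = design * sw[:, None]
    b = y * sw
    if np.linalg.matrix_rank(a) < a.shape[1]:
        raise SingularFitError("rank-deficient kinetic design matrix")
    coef, _, _, _ = np.linalg.lstsq(a, b, rcond=None)
    resid = y - design @ coef
    return coef, float(np.sum(w * resid**2))


def _check_pair(target: TAC, reference: TAC) -> None:
    if target.frame_schedule.n_frames != reference.frame_schedule.n_frames or not np.allclose(
        target.frame_schedule.start_s, reference.frame_schedule.start_s
    ):
        raise ValueError("target and reference TACs must share a frame schedule")


def mrtm_baseline_fit(
    target: TAC,
    reference: TAC,
    k2_prime: float | None = None,
    weights: str | np.ndarray = "frame_duration",
) -> KineticFit:
    """Baseline multilinear reference-tissue fit of one TAC.

    With ``k2_prime`` given (per minute), the design has two columns
    and k2 = R1*k2' is implied; with ``k2_prime=None`` the unconstrained
    three-parameter form is solved (use this once on a whole-striatum
    TAC to estimate k2', then fix it everywhere else).
    """
    _check_pair(target, reference)
    fs = target.frame_schedule
    t_mid = fs.midpoints_s
    w = _frame_weights(fs, weights)
    y = target.activity
    c_r = reference.activity
    int_r = _running_integral_min(t_mid, c_r)
    int_t = _running_integral_min(t_mid, y)

    if k2_prime is None:
        design = np.column_stack([c_r, int_r, -int_t])
        coef, rss = _wlstsq(design, y, w)
        r1, k2, k2a = (float(c) for c in coef)
        k2p = k2 / r1 if r1 != 0 else np.nan
    else:
        design = np.column_stack([c_r + k2_prime * int_r, -int_t])
        coef, rss = _wlstsq(design, y, w)
        r1, k2a = (float(c) for c in coef)
        k2 = r1 * k2_prime
        k2p = float(k2_prime)

    fitted = design @ coef
    bp = k2 / k2a - 1.0 if k2a != 0 else np.nan
    return KineticFit(
        r1=r1,
        k2_per_min=k2,
        k2a_per_min=k2a,
        k2_prime_per_min=k2p,
        bp_nd_baseline=float(bp),
        gamma_per_min=0.0,
        basis=None,
        basis_index=None,
        rss=rss,
        f_stat=None,
        gamma_clamped=False,
        fitted=fitted,
        target=target,
        reference=reference,
        weights=w,
    )


def build_reversal_basis(
    reversal_time_s: float,
    n_basis: int = 5,
    peak_offsets_min: tuple[float, ...] | None = None,
    sharpness: float = 1.0,
    scan_end_s: float | None = None,
) -> list[GammaResponse]:
    """Unit-peak gamma-variate basis set locked to a reversal onset.

    All responses start at ``reversal_time_s``; peak times span
    {1, 2, 4, 8, 12} min after onset by default (geometrically spaced
    over the same range for other ``n_basis``), covering fast to slow
    release shapes.
    """
    if peak_offsets_min is None:
        if n_basis == len(DEFAULT_PEAK_OFFSETS_MIN):
            peak_offsets_min = DEFAULT_PEAK_OFFSETS_MIN
        else:
            peak_offsets_min = tuple(
                np.geomspace(DEFAULT_PEAK_OFFSETS_MIN[0], DEFAULT_PEAK_OFFSETS_MIN[-1], n_basis)
            )
    if len(peak_offsets_min) != n_basis:
        raise ValueError("peak_offsets_min length must equal n_basis")
    if scan_end_s is not None:
        if not 0 <= reversal_time_s < scan_end_s:
            raise ValueError("reversal_time_s must lie within the scan")
        if reversal_time_s + max(peak_offsets_min) * 60.0 > scan_end_s:
            raise ValueError("basis peak grid exceeds the scan end")
    return [
        GammaResponse(reversal_time_s, reversal_time_s + off * 60.0, sharpness)
        for off in peak_offsets_min
    ]


def lp_ntpet_fit(
    target: TAC,
    reference: TAC,
    basis_set: list[GammaResponse],
    k2_prime: float,
    weights: str | np.ndarray = "frame_duration",
) -> KineticFit:
    """lp-ntPET fit: baseline kinetics plus one reversal-locked release
    basis, chosen to minimise the (weighted) residual sum of squares.

    The release magnitude gamma is constrained >= 0; if the best linear
    solution for a basis is negative, that candidate collapses to the
    baseline fit (gamma clamped to 0 and flagged). Ties between bases
    break toward the earliest peak. ``f_stat`` is the extra-sum-of-
    squares F of the winning release model against baseline.
    """
    if not basis_set:
        raise ValueError("basis_set must be non-empty")
    _check_pair(target, reference)
    fs = target.frame_schedule
    t_mid = fs.midpoints_s
    w = _frame_weights(fs, weights)
    y = target.activity
    c_r = reference.activity
    int_r = _running_integral_min(t_mid, c_r)
    int_t = _running_integral_min(t_mid, y)
    base_col = c_r + k2_prime * int_r

    baseline = mrtm_baseline_fit(target, reference, k2_prime, weights)

    candidates = []
    for idx, basis in enumerate(basis_set):
        int_bt = _running_integral_min(t_mid, basis.value(t_mid) * y)
        design = np.column_stack([base_col, -int_t, -int_bt])
        try:
            coef, rss = _wlstsq(design, y, w)
        except SingularFitError:
            coef, rss = None, np.inf
        if coef is None or coef[2] < 0:
            # constrained optimum sits on the gamma = 0 boundary
            candidates.append((baseline.rss, idx, basis, None, True))
        else:
            candidates.append((rss, idx, basis, coef, False))

    # min rss; tie-break toward the earliest basis peak
    candidates.sort(key=lambda c: (c[0], c[2].peak_s))
    rss, idx, basis, coef, clamped = candidates[0]

    if clamped:
        f_stat = f_statistic(baseline.rss, baseline.rss, 2, 3, fs.n_frames)
        return replace(
            baseline,
            basis=basis,
            basis_index=idx,
            f_stat=f_stat,
            gamma_clamped=True,
        )

    r1, k2a, gamma = (float(c) for c in coef)
    k2 = r1 * k2_prime
    f_stat = f_statistic(baseline.rss, rss, 2, 3, fs.n_frames)
    design = np.column_stack(
        [base_col, -int_t, -_running_integral_min(t_mid, basis.value(t_mid) * y)]
    )
    return KineticFit(
        r1=r1,
        k2_per_min=k2,
        k2a_per_min=k2a,
        k2_prime_per_min=float(k2_prime),
        bp_nd_baseline=k2 / k2a - 1.0,
        gamma_per_min=gamma,
        basis=basis,
        basis_index=idx,
        rss=rss,
        f_stat=f_stat,
        gamma_clamped=False,
        fitted=design @ coef,
        target=target,
        reference=reference,
        weights=w,
    )


def f_statistic(
    rss_base: float, rss_full: float, p_base: int, p_full: int, n_frames: int
) -> float:
    """Extra-sum-of-squares F statistic between nested linear models."""
    if rss_full <= 0 or rss_base < rss_full - 1e-12:
        raise ValueError("require rss_base >= rss_full > 0")
    if p_full <= p_base or n_frames <= p_full:
        raise ValueError("degenerate degrees of freedom")
    num = max(rss_base - rss_full, 0.0) / (p_full - p_base)
    den = rss_full / (n_frames - p_full)
    return num / den


def occupancy_curve(
    fit: KineticFit,
    pre_window: tuple[float, float],
    post_window: tuple[float, float],
    dt_s: float = 1.0,
) -> OccupancyCurve:
    """Receptor occupancy over time from a kinetic fit.

    ``pre_bp`` is the mean dynamic BP_ND over ``pre_window`` (seconds);
    the peak occupancy is the curve maximum over ``post_window``;
    ``post_bp`` is the BP_ND at that peak.
    """
    t0 = min(pre_window[0], post_window[0])
    t1 = max(pre_window[1], post_window[1])
    times = np.arange(t0, t1 + dt_s / 2, dt_s)
    bp_t = fit.dynamic_bp(times)

    pre_mask = (times >= pre_window[0]) & (times <= pre_window[1])
    pre_bp = float(bp_t[pre_mask].mean())
    if pre_bp <= 0:
        raise ValueError("pre-reversal BP_ND must be > 0 for occupancy")
    occ = (pre_bp - bp_t) / pre_bp * 100.0

    post_mask = (times >= post_window[0]) & (times <= post_window[1])
    post_idx = np.flatnonzero(post_mask)
    peak_local = int(np.argmax(occ[post_idx]))
    peak_idx = post_idx[peak_local]
    return OccupancyCurve(
        times_s=times,
        occupancy_pct=occ,
        peak_occupancy_pct=float(occ[peak_idx]),
        peak_time_s=float(times[peak_idx]),
        pre_bp=pre_bp,
        post_bp=float(bp_t[peak_idx]),
    )


def predicted_path(fit: KineticFit, reference: TAC | None = None) -> TAC:
    """Model-implied TAC with the release term removed.

    Evaluates the operational equation with the fitted R1 and baseline
    efflux only, i.e. the counterfactual curve had no dopamine been
    released. For a gamma = 0 fit this equals the model fit itself.
    """
    reference = reference if reference is not None else fit.reference
    _check_pair(fit.target, reference)
    t_mid = fit.target.frame_schedule.midpoints_s
    int_r = _running_integral_min(t_mid, reference.activity)
    int_t = _running_integral_min(t_mid, fit.target.activity)
    path = (
        fit.r1 * (reference.activity + fit.k2_prime_per_min * int_r)
        - fit.k2a_per_min * int_t
    )
    return TAC(fit.target.frame_schedule, np.maximum(path, 0.0))


def temporal_smooth(tac: TAC, kernel: tuple[float, ...] = (0.25, 0.50, 0.25)) -> TAC:
    """Three-frame Gaussian temporal smoothing.

    Edges renormalise the kernel over the available frames, so a
    constant TAC is left unchanged everywhere.
    """
    if tac.frame_schedule.n_frames < 3:
        raise ValueError("need >= 3 frames to smooth")
    k = np.asarray(kernel, dtype=float)
    half = len(k) // 2
    padded = np.pad(tac.activity, half, mode="constant")
    valid = np.pad(np.ones_like(tac.activity), half, mode="constant")
    num = np.convolve(padded, k, mode="valid")
    den = np.convolve(valid, k, mode="valid")
    return TAC(tac.frame_schedule, num / den)


def voxelwise_fit(
    grid: np.ndarray,
    reference: TAC,
    basis_set: list[GammaResponse],
    k2_prime: float | None = None,
    f_threshold: float = F_MASK_DEFAULT,
    weights: str | np.ndarray = "frame_duration",
) -> VoxelwiseResult:
    """Fit lp-ntPET to every voxel of a (nx, ny, nz, n_frames) grid.

    When ``k2_prime`` is None it is first estimated from the grid-mean
    TAC (the "whole striatum") by an unconstrained baseline fit, then
    fixed for all voxels. Voxels with F above ``f_threshold`` form the
    displacement mask; the two-step refinement refits the model on the
    average TAC over masked voxels (``roi_fit``; None when the mask is
    empty — a valid, explicitly reported outcome).
    """
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 4 or grid.shape[3] != reference.frame_schedule.n_frames:
        raise ValueError("grid must be (nx, ny, nz, n_frames) matching the reference")
    fs = reference.frame_schedule

    if k2_prime is None:
        whole = TAC(fs, grid.reshape(-1, fs.n_frames).mean(axis=0))
        k2_prime = mrtm_baseline_fit(whole, reference, None, weights).k2_prime_per_min

    shape = grid.shape[:3]
    f_map = np.zeros(shape)
    gamma_map = np.zeros(shape)
    for idx in np.ndindex(shape):
        fit = lp_ntpet_fit(TAC(fs, grid[idx]), reference, basis_set, k2_prime, weights)
        f_map[idx] = fit.f_stat if fit.f_stat is not None else 0.0
        gamma_map[idx] = fit.gamma_per_min
    mask = f_map > f_threshold

    roi_fit = None
    if mask.any():
        roi_tac = TAC(fs, grid[mask].mean(axis=0))
        roi_fit = lp_ntpet_fit(roi_tac, reference, basis_set, k2_prime, weights)
    return VoxelwiseResult(
        f_map=f_map, gamma_map=gamma_map, mask=mask, roi_fit=roi_fit, f_threshold=f_threshold
    )
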