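"""Forward simulation of reference and target time-activity curves.

The target tissue follows the one-tissue reference model used by
reference-tissue kinetic analysis,

    dC_T/dt = R1 dC_R/dt + k2 C_R - [k2a + gamma * B(t)] C_T,

with k2a = k2 / (1 + BP_ND) and an optional time-varying efflux term
gamma * B(t) (a unit-peak gamma-variate response) representing
displacement of the tracer by endogenous dopamine released at a reward
reversal. The reference input C_R is a smooth analytic bi-exponential
(uptake minus washout), standing in for a cerebellar grey-matter curve.
The equation is integrated by classic RK4 on a fine grid, averaged over
the acquisition frames, and optionally corrupted by zero-mean Gaussian
noise whose variance scales with activity over frame duration — the
standard model for decay-corrected PET.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .tac import TAC, FrameSchedule, GammaResponse

__all__ = [
    "RefInputParams",
    "BaseKineticParams",
    "ReleaseSpec",
    "TacSimSpec",
    "TacTruth",
    "simulate_tac",
    "simulate_voxel_grid",
    "gamma_for_peak_occupancy",
]

VOXEL_NOISE_SCALE = 0.1  # represents HYPR-denoised voxel TACs


@dataclass(frozen=True)
class RefInputParams:
    """Analytic reference-region curve C_R(t) = A (e^{-a t} - e^{-b t}),
    scaled so the maximum equals ``peak_activity`` (arbitrary units)."""

    peak_activity: float = 30.0
    uptake_per_min: float = 1.5
    washout_per_min: float = 0.04

    def __post_init__(self) -> None:
        if self.peak_activity <= 0:
            raise ValueError("peak_activity must be > 0")
        if not 0 < self.washout_per_min < self.uptake_per_min:
            raise ValueError("require 0 < washout_per_min < uptake_per_min")

    def _scale(self) -> float:
        a, b = self.washout_per_min, self.uptake_per_min
        t_peak = np.log(b / a) / (b - a)
        return self.peak_activity / (np.exp(-a * t_peak) - np.exp(-b * t_peak))

    def value(self, t_s: np.ndarray | float) -> np.ndarray:
        t = np.asarray(t_s, dtype=float) / 60.0
        a, b = self.washout_per_min, self.uptake_per_min
        return self._scale() * (np.exp(-a * t) - np.exp(-b * t))

    def derivative(self, t_s: np.ndarray | float) -> np.ndarray:
        """dC_R/dt in units of activity per second."""
        t = np.asarray(t_s, dtype=float) / 60.0
        a, b = self.washout_per_min, self.uptake_per_min
        return self._scale() * (-a * np.exp(-a * t) + b * np.exp(-b * t)) / 60.0


@dataclass(frozen=True)
class BaseKineticParams:
    """Ground-truth baseline kinetics of the target tissue."""

    r1: float = 1.0
    k2_per_min: float = 0.35
    bp_nd: float = 2.5

    def __post_init__(self) -> None:
        if self.r1 <= 0 or self.k2_per_min <= 0 or self.bp_nd <= 0:
            raise ValueError("R1, k2 and BP_ND must all be > 0")

    @property
    def k2a_per_min(self) -> float:
        return self.k2_per_min / (1.0 + self.bp_nd)


@dataclass(frozen=True)
class ReleaseSpec:
    """Reversal-locked dopamine-release term gamma * B(t)."""

    onset_s: float
    peak_s: float
    magnitude: float  # gamma, 1/min
    sharpness: float = 1.0

    def __post_init__(self) -> None:
        if self.magnitude < 0:
            raise ValueError("release magnitude must be >= 0")

    def basis(self) -> GammaResponse:
        return GammaResponse(self.onset_s, self.peak_s, self.sharpness)


@dataclass(frozen=True)
class TacSimSpec:
    """Complete specification of one simulated reference/target TAC pair."""

    frame_schedule: FrameSchedule = field(default_factory=FrameSchedule.default_68min)
    ref_params: RefInputParams = field(default_factory=RefInputParams)
    base_params: BaseKineticParams = field(default_factory=BaseKineticParams)
    release: ReleaseSpec | None = None
    noise_scale: float = 0.0
    ref_noise_scale: float = 0.0
    seed: int = 0
    fine_dt_s: float = 0.5

    def __post_init__(self) -> None:
        if self.noise_scale < 0 or self.ref_noise_scale < 0:
            raise ValueError("noise scales must be >= 0")


@dataclass(frozen=True)
class TacTruth:
    """Ground truth record returned alongside a simulated TAC pair."""

    r1: float
    k2_per_min: float
    bp_nd: float
    gamma_per_min: float
    onset_s: float | None
    peak_s: float | None
    sharpness: float
    clipped_frames: int

    def dynamic_bp(self, t_s: np.ndarray) -> np.ndarray:
        k2a = self.k2_per_min / (1.0 + self.bp_nd)
        if self.gamma_per_min > 0 and self.onset_s is not None:
            basis = GammaResponse(self.onset_s, self.peak_s, self.sharpness)
            k2a_t = k2a + self.gamma_per_min * basis.value(t_s)
        else:
            k2a_t = np.full_like(np.asarray(t_s, dtype=float), k2a)
        return self.k2_per_min / k2a_t - 1.0

    def occupancy_pct(self, t_s: np.ndarray) -> np.ndarray:
        return (self.bp_nd - self.dynamic_bp(t_s)) / self.bp_nd * 100.0

    @property
    def peak_occupancy_pct(self) -> float:
        if self.gamma_per_min <= 0 or self.onset_s is None:
            return 0.0
        return float(self.occupancy_pct(np.asarray(self.peak_s)))


def _frame_average(fine_t: np.ndarray, fine_y: np.ndarray, fs: FrameSchedule) -> np.ndarray:
    """Average a finely sampled curve over each acquisition frame."""
    out = np.empty(fs.n_frames)
    for i, (s, e) in enumerate(zip(fs.start_s, fs.end_s)):
        m = (fine_t >= s - 1e-9) & (fine_t <= e + 1e-9)
        out[i] = np.trapezoid(fine_y[m], fine_t[m]) / (e - s)
    return out


def frame_noise_sd(activity: np.ndarray, durations_s: np.ndarray, noise_scale: float) -> np.ndarray:
    """Per-frame Gaussian noise SD: variance = scale^2 * C / dt(min)."""
    c = np.maximum(np.asarray(activity, dtype=float), 1e-6)
    return noise_scale * np.sqrt(c / (np.asarray(durations_s) / 60.0))


def simulate_tac(spec: TacSimSpec) -> tuple[TAC, TAC, TacTruth]:
    """Simulate a (reference, target) TAC pair with known ground truth.

    The compartment equation is integrated by RK4 at ``fine_dt_s``
    resolution from C_T(0) = 0, frame-averaged, then noise-corrupted.
    Negative post-noise activities are clipped at zero and counted in
    the returned truth record. Deterministic given ``spec.seed``.
    """
    fs = spec.frame_schedule
    ref, base = spec.ref_params, spec.base_params
    basis = spec.release.basis() if spec.release is not None else None
    gamma = spec.release.magnitude if spec.release is not None else 0.0

    r1 = base.r1
    k2_s = base.k2_per_min / 60.0
    k2a_s = base.k2a_per_min / 60.0
    gamma_s = gamma / 60.0

    t_end = float(fs.end_s[-1])
    n_steps = int(round(t_end / spec.fine_dt_s))
    fine_t = np.linspace(0.0, t_end, n_steps + 1)

    def deriv(t: float, c_t: float) -> float:
        k2a_eff = k2a_s + (gamma_s * float(basis.value(t)) if basis is not None else 0.0)
        return float(ref.derivative(t)) * r1 + k2_s * float(ref.value(t)) - k2a_eff * c_t

    c_t = np.empty_like(fine_t)
    c_t[0] = 0.0
    h = spec.fine_dt_s
    for i in range(n_steps):
        t, y = fine_t[i], c_t[i]
        k1 = deriv(t, y)
        k2_ = deriv(t + h / 2, y + h / 2 * k1)
        k3 = deriv(t + h / 2, y + h / 2 * k2_)
        k4 = deriv(t + h, y + h * k3)
        c_t[i + 1] = y + h / 6 * (k1 + 2 * k2_ + 2 * k3 + k4)

    target_clean = _frame_average(fine_t, c_t, fs)
    ref_clean = _frame_average(fine_t, np.asarray(ref.value(fine_t)), fs)

    rng = np.random.default_rng([spec.seed, 0x7AC])
    clipped = 0
    if spec.noise_scale > 0:
        sd = frame_noise_sd(target_clean, fs.durations_s, spec.noise_scale)
        target = target_clean + rng.normal(0.0, 1.0, fs.n_frames) * sd
        clipped += int((target < 0).sum())
        target = np.maximum(target, 0.0)
    else:
        target = target_clean
    if spec.ref_noise_scale > 0:
        sd = frame_noise_sd(ref_clean, fs.durations_s, spec.ref_noise_scale)
        ref_act = ref_clean + rng.normal(0.0, 1.0, fs.n_frames) * sd
        clipped += int((ref_act < 0).sum())
        ref_act = np.maximum(ref_act, 0.0)
    else:
        ref_act = ref_clean

    truth = TacTruth(
        r1=r1,
        k2_per_min=base.k2_per_min,
        bp_nd=base.bp_nd,
        gamma_per_min=gamma,
        onset_s=spec.release.onset_s if spec.release else None,
        peak_s=spec.release.peak_s if spec.release else None,
        sharpness=spec.release.sharpness if spec.release else 1.0,
        clipped_frames=clipped,
    )
    return TAC(fs, ref_act), TAC(fs, target), truth


def simulate_voxel_grid(
    shape: tuple[int, int, int],
    release_block: tuple[slice, slice, slice] | None,
    spec: TacSimSpec,
    noise_scale: float = VOXEL_NOISE_SCALE,
    seed: int = 0,
) -> tuple[TAC, np.ndarray, np.ndarray]:
    """Simulate a small 3-D phantom of voxel TACs.

    Voxels inside ``release_block`` follow ``spec`` (including its
    release term); all others follow the release-free baseline model
    with the same kinetics. Every voxel gets independent Gaussian noise
    with the frame-duration-scaled variance model at ``noise_scale``
    (the default represents denoised voxel data). Returns the noiseless
    reference TAC, the (nx, ny, nz, n_frames) grid, and the boolean
    ground-truth release mask. Deterministic given ``seed``.
    """
    clean_spec = replace(spec, noise_scale=0.0, ref_noise_scale=0.0)
    ref_tac, target_release, _ = simulate_tac(clean_spec)
    _, target_null, _ = simulate_tac(replace(clean_spec, release=None))
    fs = spec.frame_schedule
    truth_mask = np.zeros(shape, dtype=bool)
    if release_block is not None:
        truth_mask[release_block] = True
    rng = np.random.default_rng([seed, 0xF4A7])
    grid = np.empty(shape + (fs.n_frames,))
    for idx in np.ndindex(shape):
        clean = target_release.activity if truth_mask[idx] else target_null.activity
        sd = frame_noise_sd(clean, fs.durations_s, noise_scale)
        grid[idx] = np.maximum(clean + rng.normal(size=fs.n_frames) * sd, 0.0)
    return ref_tac, grid, truth_mask


def gamma_for_peak_occupancy(
    peak_occupancy_pct: float, k2_per_min: float, bp_nd: float
) -> float:
    """Release magnitude gamma whose unit-peak response yields a given
    peak receptor occupancy (%).

    At the response peak B = 1, BP drops to BP_ND * (1 - occ/100), so
    gamma = k2 / (1 + BP_peak) - k2a.
    """
    if not 0 <= peak_occupancy_pct < 100:
        raise ValueError("peak occupancy must be in [0, 100)")
    k2a = k2_per_min / (1.0 + bp_nd)
    bp_peak = bp_nd * (1.0 - peak_occupancy_pct / 100.0)
    return k2_per_min / (1.0 + bp_peak) - k2a
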