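"""Generative conditional-intensity models for the five receptive-field classes.

Class 0 neurons fire as a homogeneous Poisson process; class 1 adds a Gaussian
place field over linearized position; class 2 multiplies the place field by an
exponential speed gain; class 3 adds a directional gain (+1 inbound, -1
outbound in the exponent); class 4 (place x speed x direction x theta phase)
has no closed-form parametric simulator here — it is sampled either from a
fitted GLM (:func:`sample_from_glm`) or, optionally, from the class-3 form
with per-quadrant theta-phase multipliers.

Spike counts are drawn per bin as Poisson with mean ``lambda(t) * dt``, which
keeps the generator consistent with the discrete-time Poisson GLM likelihood
used for fitting (and stays valid when ``lambda * dt > 1``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .behavior import Trajectory

__all__ = [
    "SimNeuronParams",
    "SpikeTrain",
    "UnsupportedClassError",
    "draw_sim_params",
    "eval_intensity",
    "sample_spikes",
    "sample_neuron",
    "sample_from_glm",
]

#: fixed speed gain per (cm/s) for class >= 2
GAMMA_SPEED = 0.05
#: fixed direction gain for class >= 3
ETA_DIRECTION = 0.5


class UnsupportedClassError(ValueError):
    """Raised when a parametric simulator is requested for a class that has none."""


@dataclass
class SimNeuronParams:
    """Generative intensity parameters for one simulated neuron.

    Fields beyond those a class uses are ignored: class 0 uses only ``alpha``
    (constant rate); classes 1-3 use ``alpha`` (peak rate), ``a`` (field
    center, cm) and ``b`` (field width, cm); ``gamma`` applies from class 2 and
    ``eta`` from class 3.  ``phase_gains`` (log-multipliers for the four theta
    quadrants) applies only to the optional class-4 parametric form.
    """

    class_id: int
    alpha: float
    a: float = np.nan
    b: float = np.nan
    gamma: float = GAMMA_SPEED
    eta: float = ETA_DIRECTION
    phase_gains: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.class_id not in (0, 1, 2, 3, 4):
            raise ValueError(f"class_id must be 0..4, got {self.class_id}")
        if self.alpha < 0:
            raise ValueError("alpha must be nonnegative")
        if self.class_id >= 1:
            if not (0 <= self.a <= 300):
                raise ValueError("place-field center a must lie in [0, 300] cm")
            if not self.b > 0:
                raise ValueError("place-field width b must be positive")


@dataclass
class SpikeTrain:
    """Per-bin spike counts aligned to a trajectory."""

    counts: np.ndarray
    dt_s: float = 0.01

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 1:
            raise ValueError("counts must be one-dimensional")
        if np.any(self.counts < 0):
            raise ValueError("spike counts must be nonnegative")
        self.counts = self.counts.astype(np.int64)

    def __len__(self) -> int:
        return len(self.counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def mean_rate(self) -> float:
        """Empirical mean firing rate in spikes/s."""
        return self.total / (len(self.counts) * self.dt_s)


def draw_sim_params(
    class_id: int, rng_seed: int, allow_class4: bool = False
) -> SimNeuronParams:
    """Draw generative parameters for one simulated neuron.

    Class 0: constant rate alpha ~ U[0, 200] spikes/s.  Classes 1-3:
    alpha ~ U[6, 9] spikes/s, center a ~ U[10, 290] cm, width b ~ U[10, 100]
    cm, with gamma = 0.05 fixed (classes >= 2) and eta = 0.5 fixed (class 3).
    Class 4 has no stated parametric distribution; by default it raises and
    directs callers to :func:`sample_from_glm`.  With ``allow_class4=True`` a
    class-3 parameter set is extended with per-quadrant theta log-gains
    c_k ~ U[-0.5, 0.5].
    """
    rng = np.random.default_rng(rng_seed)
    if class_id == 0:
        return SimNeuronParams(class_id=0, alpha=rng.uniform(0.0, 200.0))
    if class_id in (1, 2, 3) or (class_id == 4 and allow_class4):
        alpha = rng.uniform(6.0, 9.0)
        a = rng.uniform(10.0, 290.0)
        b = rng.uniform(10.0, 100.0)
        phase_gains = None
        if class_id == 4:
            phase_gains = rng.uniform(-0.5, 0.5, size=4)
        return SimNeuronParams(
            class_id=class_id, alpha=alpha, a=a, b=b, phase_gains=phase_gains
        )
    if class_id == 4:
        raise UnsupportedClassError(
            "class 4 has no parametric simulator; sample from a fitted GLM via "
            "sample_from_glm, or pass allow_class4=True for the spline-free "
            "phase-quadrant fallback"
        )
    raise ValueError(f"class_id must be 0..4, got {class_id}")


def eval_intensity(params: SimNeuronParams, traj: Trajectory) -> np.ndarray:
    """Evaluate the conditional intensity lambda(t) (spikes/s) on a trajectory.

    lambda_0 = alpha;
    lambda_1 = alpha * exp(-(x-a)^2 / (2 b^2));
    lambda_2 = lambda_1 * exp(gamma * s);
    lambda_3 = lambda_2 * exp(eta * d_pm), d_pm = +1 inbound / -1 outbound;
    lambda_4 = lambda_3 * exp(c_k) with c_k the log-gain of the occupied
    theta-phase quadrant (optional parametric form).
    """
    for name in ("x", "s", "phi"):
        if np.any(~np.isfinite(getattr(traj, name))):
            raise ValueError(f"trajectory covariate {name!r} contains non-finite values")
    if params.class_id == 0:
        return np.full(traj.T, params.alpha)
    lam = params.alpha * np.exp(-((traj.x - params.a) ** 2) / (2.0 * params.b**2))
    if params.class_id >= 2:
        lam = lam * np.exp(params.gamma * traj.s)
    if params.class_id >= 3:
        d_pm = np.where(traj.d == 1, 1.0, -1.0)
        lam = lam * np.exp(params.eta * d_pm)
    if params.class_id == 4:
        if params.phase_gains is None:
            raise UnsupportedClassError(
                "class-4 intensity needs phase_gains or a fitted GLM"
            )
        quadrant = phase_quadrant(traj.phi)
        lam = lam * np.exp(np.asarray(params.phase_gains)[quadrant])
    if np.any(~np.isfinite(lam)):
        raise FloatingPointError("non-finite intensity value")
    return lam


def phase_quadrant(phi: np.ndarray) -> np.ndarray:
    """Index of the theta-phase quadrant: [-pi,-pi/2), [-pi/2,0), [0,pi/2), [pi/2,pi)."""
    return np.clip(((np.asarray(phi) + np.pi) // (np.pi / 2)).astype(int), 0, 3)


def sample_spikes(rate: np.ndarray, dt_s: float = 0.01, rng_seed: int = 0) -> SpikeTrain:
    """Draw per-bin Poisson spike counts with mean ``rate[t] * dt_s``."""
    rate = np.asarray(rate, dtype=float)
    if np.any(~np.isfinite(rate)) or np.any(rate < 0):
        raise ValueError("rate series must be finite and nonnegative")
    rng = np.random.default_rng(rng_seed)
    counts = rng.poisson(rate * dt_s)
    return SpikeTrain(counts=counts, dt_s=dt_s)


def sample_neuron(params: SimNeuronParams, traj: Trajectory, rng_seed: int = 0) -> SpikeTrain:
    """Convenience: evaluate the class intensity on `traj` and sample spikes."""
    lam = eval_intensity(params, traj)
    return sample_spikes(lam, traj.dt_s, rng_seed)


def sample_from_glm(fit, traj: Trajectory, rng_seed: int = 0) -> SpikeTrain:
    """Simulate a spike train from a fitted Poisson GLM (empirical augmentation).

    Rebuilds the fit's design matrix on `traj` (same covariate requirements as
    the original fit; a missing covariate raises), computes the per-bin mean
    ``exp(X theta) * dt`` and samples Poisson counts.  Works for any fitted
    model class 0-4.
    """
    from .ppglm import build_design  # local import to avoid a cycle

    X, _ = build_design(fit.class_id, traj, fit.basis)
    if X.shape[1] != fit.p:
        raise ValueError(
            f"design built from trajectory has {X.shape[1]} columns but fit has p={fit.p}"
        )
    mean = np.exp(X @ fit.theta) * traj.dt_s
    rng = np.random.default_rng(rng_seed)
    return SpikeTrain(counts=rng.poisson(mean), dt_s=traj.dt_s)
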