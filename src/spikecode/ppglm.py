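"""Point-process GLM core: place-field bases, design matrices, IRLS fitting,
and step-up model identification.

The discrete-time approximation treats each 10 ms bin's spike count as Poisson
with mean ``lambda(t) * dt`` and ``log lambda(t) = X(t) theta``; the log-dt
offset enters the likelihood, so coefficients are on the spikes/s scale.  The
Poisson log-likelihood with a log link is convex in theta, so Newton/IRLS
iterations converge to the unique maximum whenever it exists.

Model classes (nested covariate groups, all sharing one position basis):

* class 0 - intercept only (homogeneous Poisson);
* class 1 - intercept + spline place field g_i(x);
* class 2 - place field gated by running, g_i(x) * I{s > 2 cm/s};
* class 3 - class-2 columns split by direction (inbound/outbound);
* class 4 - class-3 columns split by the four theta-phase quadrants.

A neuron's coding class is assigned by step-up likelihood-ratio testing:
starting at class 0, each richer model is accepted while its LR test against
the current model is significant; the assigned class is the last accepted
model.  The class-1 -> class-2 comparison is not nested (the spline columns
are replaced by speed-gated ones, same parameter count); it is scored on the
likelihood difference with one degree of freedom and a negative statistic
counts as no improvement.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.special import gammaln
from scipy.stats import chi2

from .behavior import SPEED_THRESHOLD_CMPS, Trajectory
from .encoder import SpikeTrain, phase_quadrant
from .splines import SplineBasis, spline_design

__all__ = [
    "GLMFit",
    "OccupancyHistogram",
    "ModelIdentificationResult",
    "SeparationWarning",
    "occupancy_histogram",
    "place_field_peak",
    "select_control_points",
    "default_basis",
    "build_design",
    "fit_poisson_glm",
    "fit_class",
    "lr_test",
    "step_up_identify",
    "fit_report",
]

#: default histogram bin width (cm)
DEFAULT_BIN_CM = 5.0
#: minimum occupancy for a defined rate bin (s)
MIN_DWELL_S = 0.5
#: default cap on automatically selected control points
DEFAULT_MAX_POINTS = 8


class SeparationWarning(UserWarning):
    """Diverging coefficients: covariates (nearly) separate spikes from silence."""


@dataclass
class GLMFit:
    """A fitted Poisson GLM for one neuron and one model class."""

    class_id: int
    theta: np.ndarray
    loglik: float
    fisher_info: np.ndarray
    p: int
    basis: Optional[SplineBasis]
    converged: bool
    n_iter: int
    column_names: list = field(default_factory=list)
    #: log-likelihood converged but some coefficient diverged (unbounded
    #: maximum-likelihood direction, e.g. a spike-free track region)
    separated: bool = False
    #: numerical rank of the design matrix; the intercept is collinear with a
    #: partition-of-unity spline block, so rank can be below p
    rank: int = -1

    def __post_init__(self) -> None:
        if self.rank < 0:
            self.rank = self.p

    def std_errors(self) -> np.ndarray:
        """Coefficient standard errors from the observed Fisher information."""
        cov = np.linalg.pinv(self.fisher_info)
        return np.sqrt(np.clip(np.diag(cov), 0.0, None))


@dataclass
class OccupancyHistogram:
    """Occupancy-normalized firing-rate map over linearized position."""

    bin_edges: np.ndarray
    occupancy_s: np.ndarray
    spike_counts: np.ndarray
    rate: np.ndarray  # spikes/s; NaN where occupancy < MIN_DWELL_S

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def defined(self) -> np.ndarray:
        return ~np.isnan(self.rate)


@dataclass
class ModelIdentificationResult:
    """Outcome of the sequential step-up identification for one neuron."""

    assigned_class: int
    lr_stats: list
    p_values: list
    dofs: list
    alpha: float
    fits: list = field(default_factory=list)
    diagnostics: list = field(default_factory=list)


def occupancy_histogram(
    spikes: SpikeTrain,
    traj: Trajectory,
    bin_cm: float = DEFAULT_BIN_CM,
    min_dwell_s: float = MIN_DWELL_S,
) -> OccupancyHistogram:
    """Occupancy-normalized place-field histogram over the linearized track."""
    if bin_cm <= 0:
        raise ValueError("bin_cm must be positive")
    if len(spikes) != traj.T:
        raise ValueError("spike train and trajectory lengths differ")
    edges = np.arange(0.0, 300.0 + bin_cm, bin_cm)
    idx = np.clip(np.digitize(traj.x, edges) - 1, 0, len(edges) - 2)
    occ = np.bincount(idx, minlength=len(edges) - 1) * traj.dt_s
    cnt = np.bincount(idx, weights=spikes.counts, minlength=len(edges) - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        rate = np.where(occ >= min_dwell_s, cnt / np.where(occ > 0, occ, np.nan), np.nan)
    return OccupancyHistogram(
        bin_edges=edges, occupancy_s=occ, spike_counts=cnt, rate=rate
    )


def select_control_points(
    hist: OccupancyHistogram,
    max_points: int = DEFAULT_MAX_POINTS,
    smooth_bins: int = 5,
) -> np.ndarray:
    """Automatic spline control-point placement from a rate histogram.

    Smooths the defined rate bins with a moving average, places candidate
    points at local maxima of the smoothed curve, always keeps the two track
    endpoints, and caps peak points at ``max_points`` keeping the tallest.
    Remaining capacity is filled by bisecting the largest gaps, so a flat or
    single-peak histogram still yields a basis with even coverage of the
    track.
    """
    defined = hist.defined
    if defined.sum() < 3:
        raise ValueError("need at least 3 defined histogram bins")
    if max_points < 4:
        raise ValueError("max_points must be at least 4")
    lo, hi = 0.0, 300.0
    centers = hist.centers
    r = np.where(defined, hist.rate, 0.0)
    kernel = np.ones(smooth_bins) / smooth_bins
    rs = np.convolve(r, kernel, mode="same")
    interior = []
    for i in range(1, len(rs) - 1):
        if rs[i] > rs[i - 1] and rs[i] >= rs[i + 1] and rs[i] > 0:
            interior.append((rs[i], centers[i]))
    interior.sort(reverse=True)
    n_interior = max(max_points - 2, 0)
    peaks = sorted(p for _, p in interior[:n_interior])
    pts = np.unique(np.array([lo, *peaks, hi]))
    # enforce a minimum separation of one histogram bin
    bin_w = hist.bin_edges[1] - hist.bin_edges[0]
    keep = [pts[0]]
    for p in pts[1:]:
        if p - keep[-1] >= bin_w:
            keep.append(p)
    if keep[-1] < hi:
        keep[-1] = hi
    pts = list(keep)
    # fill the largest gaps so the basis covers the whole track
    while len(pts) < max_points:
        gaps = np.diff(pts)
        g = int(np.argmax(gaps))
        if gaps[g] < 2 * bin_w:
            break
        pts.insert(g + 1, 0.5 * (pts[g] + pts[g + 1]))
    return np.asarray(pts)


def default_basis(
    spikes: SpikeTrain,
    traj: Trajectory,
    bin_cm: float = DEFAULT_BIN_CM,
    max_points: int = DEFAULT_MAX_POINTS,
) -> SplineBasis:
    """Histogram -> control points -> basis, the default automatic pipeline.

    The minimum-dwell threshold for a defined rate bin scales down for short
    sessions (2% of the session, capped at the 0.5 s default) so that brief
    recordings still yield a usable basis.
    """
    min_dwell = min(MIN_DWELL_S, 0.02 * traj.duration_s)
    hist = occupancy_histogram(spikes, traj, bin_cm, min_dwell_s=min_dwell)
    if hist.defined.sum() < 3:  # very short or near-stationary session
        hist = occupancy_histogram(spikes, traj, bin_cm, min_dwell_s=traj.dt_s)
    if hist.defined.sum() < 3:
        return SplineBasis(np.linspace(0.0, 300.0, 5))
    return SplineBasis(select_control_points(hist, max_points))


def build_design(
    class_id: int, traj: Trajectory, basis: Optional[SplineBasis]
) -> tuple[np.ndarray, list]:
    """Build the model-class design matrix and its column names.

    See the module docstring for the five class forms.  The intercept is
    always the first column.
    """
    T = traj.T
    ones = np.ones((T, 1))
    if class_id == 0:
        return ones, ["intercept"]
    if basis is None:
        raise ValueError(f"class {class_id} design requires a spline basis")
    B = spline_design(basis, traj.x)
    names_b = [f"g{i}" for i in range(basis.n_basis)]
    if class_id == 1:
        return np.hstack([ones, B]), ["intercept", *names_b]
    if traj.s is None:
        raise ValueError("class >= 2 design requires the speed covariate")
    run = (traj.s > SPEED_THRESHOLD_CMPS).astype(float)[:, None]
    if class_id == 2:
        return np.hstack([ones, B * run]), ["intercept", *(f"{n}:run" for n in names_b)]
    if traj.d is None:
        raise ValueError("class >= 3 design requires the direction covariate")
    inb = (traj.d == 1).astype(float)[:, None]
    out = 1.0 - inb
    if class_id == 3:
        cols = [B * run * inb, B * run * out]
        names = [*(f"{n}:run:in" for n in names_b), *(f"{n}:run:out" for n in names_b)]
        return np.hstack([ones, *cols]), ["intercept", *names]
    if class_id == 4:
        if traj.phi is None:
            raise ValueError("class 4 design requires the theta-phase covariate")
        quad = phase_quadrant(traj.phi)
        blocks, names = [], []
        for dlab, dmask in (("in", inb), ("out", out)):
            for k in range(4):
                pk = (quad == k).astype(float)[:, None]
                blocks.append(B * run * dmask * pk)
                names.extend(f"{n}:run:{dlab}:phi{k + 1}" for n in names_b)
        return np.hstack([ones, *blocks]), ["intercept", *names]
    raise ValueError(f"class_id must be 0..4, got {class_id}")


def _poisson_loglik(y: np.ndarray, eta: np.ndarray) -> float:
    """Exact Poisson log-likelihood with log-mean eta (includes log y! term)."""
    return float(y @ eta - np.exp(eta).sum() - gammaln(y + 1.0).sum())


def fit_poisson_glm(
    design: np.ndarray,
    spikes: SpikeTrain,
    class_id: int = 0,
    basis: Optional[SplineBasis] = None,
    column_names: Optional[Sequence[str]] = None,
    max_iter: int = 100,
    tol: float = 1e-8,
    ridge: float = 1e-8,
    coef_guard: float = 100.0,
) -> GLMFit:
    """Maximum-likelihood Poisson GLM fit by iteratively re-weighted least squares.

    The per-bin count mean is ``exp(design theta + log dt)``.  Newton steps
    solve the weighted normal equations with a small ridge jitter for rank
    safety (degenerate all-zero columns simply keep zero coefficients).  A
    step is halved while it decreases the log-likelihood.  Coefficients whose
    magnitude exceeds ``coef_guard`` trigger a separation warning and the fit
    is flagged non-converged.  The guard is set high enough that log-rates of
    genuinely unvisited-by-spikes regions (a narrow place field leaves most of
    the track at essentially zero intensity) do not trip it.
    """
    X = np.asarray(design, dtype=float)
    y = np.asarray(spikes.counts, dtype=float)
    if X.shape[0] != len(y):
        raise ValueError("design rows and spike bins differ")
    if np.any(~np.isfinite(X)):
        raise ValueError("design matrix contains non-finite values")
    T, p = X.shape
    offset = np.log(spikes.dt_s)

    theta = np.zeros(p)
    mean_rate = max(y.mean() / spikes.dt_s, 1e-8)
    theta[0] = np.log(mean_rate)  # intercept init at the marginal rate

    eta = X @ theta + offset
    ll = _poisson_loglik(y, eta)
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        mu = np.exp(eta)
        grad = X.T @ (y - mu)
        H = (X * mu[:, None]).T @ X
        H.flat[:: p + 1] += ridge
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, grad, rcond=None)[0]
        # damped Newton: halve while the likelihood decreases
        scale = 1.0
        for _ in range(30):
            theta_new = theta + scale * step
            eta_new = X @ theta_new + offset
            with np.errstate(over="ignore"):
                ll_new = _poisson_loglik(y, eta_new)
            if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                break
            scale *= 0.5
        else:
            break
        rel = abs(ll_new - ll) / max(abs(ll), 1.0)
        theta, eta, ll = theta_new, eta_new, ll_new
        if rel < tol:
            converged = True
            break

    separated = bool(np.max(np.abs(theta)) > coef_guard)
    if separated:
        warnings.warn(
            "coefficient norm guard tripped: diverging maximum-likelihood "
            "direction (perfect separation or a spike-free region); the "
            "likelihood value itself is converged" if converged else
            "coefficient norm guard tripped with a non-converged likelihood",
            SeparationWarning,
            stacklevel=2,
        )

    mu = np.exp(eta)
    fisher = (X * mu[:, None]).T @ X
    gram = X.T @ X
    evals = np.linalg.eigvalsh(gram)
    rank = int((evals > max(evals.max(), 1e-300) * 1e-10).sum())
    return GLMFit(
        class_id=class_id,
        theta=theta,
        loglik=ll,
        fisher_info=fisher,
        p=p,
        basis=basis,
        converged=converged,
        n_iter=n_iter,
        column_names=list(column_names or []),
        separated=separated,
        rank=rank,
    )


def fit_class(
    class_id: int,
    spikes: SpikeTrain,
    traj: Trajectory,
    basis: Optional[SplineBasis] = None,
    **kwargs,
) -> GLMFit:
    """Build the class design on `traj` and fit it to `spikes`."""
    if class_id > 0 and basis is None:
        basis = default_basis(spikes, traj)
    X, names = build_design(class_id, traj, basis)
    return fit_poisson_glm(
        X, spikes, class_id=class_id, basis=basis, column_names=names, **kwargs
    )


def place_field_peak(fit: GLMFit, grid_cm: float = 0.25) -> float:
    """Location (cm) of the fitted place field's peak.

    Evaluates the fitted log place field on a fine grid and refines the
    argmax by fitting a quadratic to the contiguous region within 0.5 log
    units of the maximum and taking its vertex.  Under a Gaussian field the
    log intensity is a parabola, so the vertex pools information from the
    whole field top instead of relying on the single noisiest grid point —
    important for wide, flat fields.  Falls back to the raw argmax when the
    local fit is not concave.
    """
    if fit.basis is None:
        raise ValueError("fit has no spatial basis (class 0)")
    cp = fit.basis.control_points
    xs = np.arange(cp[0], cp[-1] + grid_cm, grid_cm)
    curve = spline_design(fit.basis, xs) @ fit.theta[1 : 1 + fit.basis.n_basis]
    i0 = int(np.argmax(curve))
    top = curve >= curve[i0] - 0.5
    # contiguous window around the argmax
    lo = i0
    while lo > 0 and top[lo - 1]:
        lo -= 1
    hi = i0
    while hi < len(xs) - 1 and top[hi + 1]:
        hi += 1
    if hi - lo >= 4:
        w = slice(lo, hi + 1)
        c2, c1, _ = np.polyfit(xs[w], curve[w], 2)
        if c2 < 0:
            vertex = -c1 / (2.0 * c2)
            if xs[lo] <= vertex <= xs[hi]:
                return float(vertex)
    return float(xs[i0])


def lr_test(
    nested: GLMFit, full: GLMFit, allow_nonnested: bool = False
) -> tuple[float, int, float]:
    """Likelihood-ratio test of `full` against `nested` on the same data.

    Returns (statistic, dof, p_value) with statistic = 2 (ll_full - ll_nested)
    and a chi-square upper-tail p-value.  Degrees of freedom use the design
    *rank* difference, so collinear columns (the intercept inside a
    partition-of-unity spline block, or empty covariate cells in the phase
    crossing) do not inflate the reference distribution.  For properly nested
    models a negative statistic beyond numerical tolerance signals an
    optimizer failure and raises.  With ``allow_nonnested=True`` (the class-1
    vs class-2 comparison, equal parameter counts) the statistic is clamped
    at zero and dof = max(1, delta rank).
    """
    stat = 2.0 * (full.loglik - nested.loglik)
    dof = full.rank - nested.rank
    if allow_nonnested:
        dof = max(1, dof)
        stat = max(stat, 0.0)
    else:
        if dof <= 0:
            raise ValueError("models are not nested (full.p must exceed nested.p)")
        if stat < -1e-6 * max(1.0, abs(nested.loglik)):
            raise RuntimeError(
                "negative LR statistic for nested models: refit needed "
                f"(stat={stat:.3g})"
            )
        stat = max(stat, 0.0)
    pval = float(chi2.sf(stat, dof))
    return float(stat), int(dof), pval


def step_up_identify(
    spikes: SpikeTrain,
    traj: Trajectory,
    alpha: float = 0.01,
    basis: Optional[SplineBasis] = None,
    bin_cm: float = DEFAULT_BIN_CM,
    max_points: int = DEFAULT_MAX_POINTS,
    keep_fits: bool = False,
) -> ModelIdentificationResult:
    """Sequential step-up coding-class identification for one neuron.

    Fits classes 0 -> 1 -> 2 -> 3 -> 4 in order, accepting each richer model
    while its LR test against the current one has p < alpha; stops at the
    first non-significant step.  A non-convergent fit ends the sequence (the
    step counts as non-significant) and is recorded in the diagnostics.
    """
    if not 0 < alpha <= 1:
        raise ValueError("alpha must lie in (0, 1]")
    if basis is None:
        basis = default_basis(spikes, traj, bin_cm=bin_cm, max_points=max_points)

    current = fit_class(0, spikes, traj, basis=basis)
    fits = [current]
    lr_stats: list = []
    p_values: list = []
    dofs: list = []
    diagnostics: list = []
    assigned = 0
    for next_class in (1, 2, 3, 4):
        candidate = fit_class(next_class, spikes, traj, basis=basis)
        if not candidate.converged:
            diagnostics.append(
                f"class-{next_class} fit did not converge; step treated as "
                "non-significant"
            )
            break
        if candidate.separated:
            diagnostics.append(
                f"class-{next_class} fit has a diverging coefficient "
                "(spike-free region); likelihood converged, step evaluated"
            )
        stat, dof, pval = lr_test(
            current, candidate, allow_nonnested=(next_class == 2)
        )
        lr_stats.append(stat)
        p_values.append(pval)
        dofs.append(dof)
        fits.append(candidate)
        if pval < alpha or alpha >= 1.0:
            assigned = next_class
            current = candidate
        else:
            break
    return ModelIdentificationResult(
        assigned_class=assigned,
        lr_stats=lr_stats,
        p_values=p_values,
        dofs=dofs,
        alpha=alpha,
        fits=fits if keep_fits else [],
        diagnostics=diagnostics,
    )


def fit_report(fit: GLMFit, result: Optional[ModelIdentificationResult] = None) -> str:
    """Serialize a fit (and optionally its identification trace) as JSON."""
    rec = {
        "class_id": fit.class_id,
        "p": fit.p,
        "loglik": fit.loglik,
        "converged": bool(fit.converged),
        "separated": bool(fit.separated),
        "n_iter": fit.n_iter,
        "theta": fit.theta.tolist(),
        "std_errors": fit.std_errors().tolist(),
        "columns": fit.column_names,
        "control_points": (
            fit.basis.control_points.tolist() if fit.basis is not None else None
        ),
    }
    if result is not None:
        rec["identification"] = {
            "assigned_class": result.assigned_class,
            "alpha": result.alpha,
            "lr_stats": result.lr_stats,
            "dofs": result.dofs,
            "p_values": result.p_values,
            "diagnostics": result.diagnostics,
        }
    return json.dumps(rec, indent=2)
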