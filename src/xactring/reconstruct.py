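"""Conventional and ring-artifact-corrected inversions.

The per-time-step covariance of offset-corrupted data is
``Sigma(q) = beta^2 1 1^T + sigma^2 I``.  By the Sherman-Morrison formula
the weight

    S(q) = sigma^-2 ( I - 1 1^T / (sigma^2/beta^2 + Nd) )

whitens it; in the stripe-dominant regime (``sigma <= beta``, many
detectors) this reduces to the centering projector

    S = I - (1/Nd) 1 1^T,

which is symmetric, idempotent, and annihilates the common-offset
direction exactly: ``S 1 = 0``.  Applying S to every time column of the
sinogram (and of the modelled data inside the solver) therefore filters
the offsets out of the residual, removing the ring artifacts at no extra
cost.  The constant ``sigma^-2`` factor is dropped in this limit since it
only rescales the objective.

Three inversions are provided:

* ``reconstruct_bp``   — delay-and-sum back-projection (baseline),
* ``reconstruct_mbp``  — model back-projection ``M^T (S P)``,
* ``reconstruct_lsqr`` — matrix-free LSQR on the stacked system
  ``[S M; sqrt(alpha) L] h = [S p; 0]`` with ``L`` a discrete Laplacian.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
import scipy.sparse.linalg

from .forward import (
    OperatorSpec,
    Sinogram,
    SourceImage,
    adjoint_apply,
    forward_apply,
)
from .geometry import TimeAxis

__all__ = [
    "WeightSpec",
    "ReconConfig",
    "ConvergenceLog",
    "detector_mean_removal",
    "reconstruct_bp",
    "reconstruct_mbp",
    "reconstruct_lsqr",
    "laplacian_apply",
    "pad_sinogram",
    "crop_sinogram",
    "sweep_alpha",
]


@dataclass(frozen=True)
class WeightSpec:
    """Per-time-step whitening weight for the offset-corrupted covariance.

    ``limit`` mode applies the centering projector ``I - (1/Nd) 1 1^T``
    (offsets dominant, the production choice); ``full`` mode applies the
    exact Sherman-Morrison inverse and requires ``sigma`` and ``beta``.
    ``corrected=False`` disables weighting entirely (conventional
    reconstruction).
    """

    corrected: bool = True
    mode: Literal["limit", "full"] = "limit"
    sigma: float | None = None
    beta: float | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("limit", "full"):
            raise ValueError(f"unknown weight mode {self.mode!r}")
        if self.mode == "full" and self.corrected:
            if self.sigma is None or self.beta is None:
                raise ValueError("full weight mode requires sigma and beta")
            if self.sigma <= 0 or self.beta < 0:
                raise ValueError("sigma must be > 0 and beta >= 0")


@dataclass(frozen=True)
class ReconConfig:
    """Algorithm choice plus weighting, regularization and solver budget.

    ``reg_weight`` is dimensionless: the Laplacian penalty is internally
    scaled by the ratio of the (power-iteration estimated) data-operator
    norm to the Laplacian stencil norm, so ``reg_weight = 1`` makes the
    two blocks of the stacked operator comparable regardless of grid
    spacing or sampling rate.
    """

    operator_spec: OperatorSpec
    algorithm: Literal["BP", "MBP", "LSQR"] = "LSQR"
    weight: WeightSpec = field(default_factory=WeightSpec)
    reg_weight: float = 0.0
    max_iters: int = 50
    rel_tol: float = 1e-6

    def __post_init__(self) -> None:
        if self.reg_weight < 0:
            raise ValueError("reg_weight must be >= 0")
        if self.max_iters < 1:
            raise ValueError("max_iters must be >= 1")


@dataclass(frozen=True)
class ConvergenceLog:
    """Iteration trace of an LSQR solve (one row per recorded iterate)."""

    iterations: np.ndarray
    residual_norms: np.ndarray
    solution_norms: np.ndarray
    istop: int

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "iteration": self.iterations,
                "residual_norm": self.residual_norms,
                "solution_norm": self.solution_norms,
            }
        )


def _apply_weight_array(values: np.ndarray, spec: WeightSpec) -> np.ndarray:
    """Multiply every time column of ``values`` (Nd x Nt) by S(q)."""
    nd = values.shape[0]
    col_mean = values.mean(axis=0, keepdims=True)
    if spec.mode == "limit":
        return values - col_mean
    # full Sherman-Morrison weight
    denom = spec.sigma**2 / spec.beta**2 + nd
    return (values - (nd / denom) * col_mean) / spec.sigma**2


def detector_mean_removal(sino: Sinogram, spec: WeightSpec) -> Sinogram:
    """Apply the per-time-step weight S to the sinogram (``B = S P``).

    In ``limit`` mode this subtracts from each time column its mean over
    the active detectors, exactly annihilating any common per-column
    offset.  Idempotent in limit mode.
    """
    if sino.n_detectors < 2:
        raise ValueError("need at least 2 detectors to remove the channel mean")
    if spec.mode == "full" and (spec.sigma is None or spec.beta is None):
        raise ValueError("full weight mode requires sigma and beta")
    return sino.with_values(_apply_weight_array(sino.values, spec), tag="weighted")


def laplacian_apply(image: SourceImage) -> SourceImage:
    """5-point discrete Laplacian ``4u - sum(4-neighbours)``, zero padding.

    Dirichlet (zero) boundary keeps the stencil symmetric so the stacked
    regularized operator has a true adjoint.
    """
    if image.grid.nx < 3 or image.grid.ny < 3:
        raise ValueError("Laplacian needs a grid of at least 3x3")
    u = image.values
    out = 4.0 * u.copy()
    out[1:, :] -= u[:-1, :]
    out[:-1, :] -= u[1:, :]
    out[:, 1:] -= u[:, :-1]
    out[:, :-1] -= u[:, 1:]
    return SourceImage(out, image.grid)


def reconstruct_bp(
    sino: Sinogram, spec: OperatorSpec, use_derivative_term: bool = True
) -> SourceImage:
    """Delay-and-sum back-projection.

    Each pixel accumulates, over detectors, the back-projection term
    ``b(t) = p(t) - t dp/dt`` (or plain ``p(t)`` when
    ``use_derivative_term=False``) evaluated at the acoustic delay
    ``t = |pixel - detector| / v`` by linear interpolation in time and
    averaged over detectors.  Delays outside the sampled window
    contribute zero.
    """
    if sino.ring != spec.ring or sino.time_axis != spec.time_axis:
        raise ValueError("sinogram geometry does not match operator spec")
    ta = sino.time_axis
    v = spec.ring.sound_speed
    t = ta.times
    p = sino.values
    if use_derivative_term:
        dpdt = np.gradient(p, ta.dt, axis=1)
        b = p - t[None, :] * dpdt
    else:
        b = p
    xg, yg = spec.grid.meshgrid()
    acc = np.zeros(spec.grid.shape, dtype=float)
    for d, pos in enumerate(spec.ring.positions):
        tau = np.hypot(xg - pos[0], yg - pos[1]) / v
        acc += np.interp(tau, t, b[d], left=0.0, right=0.0)
    return SourceImage(acc / spec.ring.n_detectors, spec.grid)


def reconstruct_mbp(sino: Sinogram, config: ReconConfig) -> SourceImage:
    """Model back-projection ``h = M^T (S P)`` (or ``M^T P`` uncorrected)."""
    if config.algorithm != "MBP":
        raise ValueError("config.algorithm must be 'MBP'")
    data = sino
    if config.weight.corrected:
        data = detector_mean_removal(sino, config.weight)
    return adjoint_apply(data, config.operator_spec)


from functools import lru_cache


@lru_cache(maxsize=32)
def _operator_norm_estimate(spec: OperatorSpec, weight: WeightSpec) -> float:
    """Largest singular value of (S)M via a few power iterations.

    Deterministic (fixed internal seed) and cached per geometry/weight so
    repeated solves on one setup pay the cost once.
    """
    rng = np.random.default_rng(12345)
    grid = spec.grid
    h = rng.standard_normal(grid.shape)
    h /= np.linalg.norm(h)
    ring, ta = spec.ring, spec.time_axis
    sigma = 0.0
    for _ in range(10):
        sim = forward_apply(SourceImage(h, grid), spec).values
        if weight.corrected:
            # M^T S^T S M h; S is applied twice (S^T S = S in limit mode)
            sim = _apply_weight_array(_apply_weight_array(sim, weight), weight)
        h_new = adjoint_apply(Sinogram(sim, ring, ta, ("weighted",)), spec).values
        nrm = np.linalg.norm(h_new)
        if nrm == 0:
            return 1.0
        sigma = np.sqrt(nrm)
        h = h_new / nrm
    return float(sigma)


#: spectral norm bound of the 5-point Laplacian stencil (2D Dirichlet)
_LAPLACIAN_NORM = 8.0


def _stacked_operator(
    config: ReconConfig, template: Sinogram
) -> scipy.sparse.linalg.LinearOperator:
    """LinearOperator for ``[S M; sqrt(alpha) L]`` acting on flattened images."""
    spec = config.operator_spec
    grid = spec.grid
    n = grid.n_pixels
    m_data = spec.n_data
    alpha = config.reg_weight
    with_reg = alpha > 0
    if with_reg:
        scale = _operator_norm_estimate(spec, config.weight) / _LAPLACIAN_NORM
        sqrt_a = float(np.sqrt(alpha)) * scale
    else:
        sqrt_a = 0.0
    m = m_data + (n if with_reg else 0)
    wspec = config.weight

    def matvec(h_flat: np.ndarray) -> np.ndarray:
        img = SourceImage(h_flat.reshape(grid.shape), grid)
        sim = forward_apply(img, spec).values
        if wspec.corrected:
            sim = _apply_weight_array(sim, wspec)
        if not with_reg:
            return sim.reshape(-1)
        reg = sqrt_a * laplacian_apply(img).values.reshape(-1)
        return np.concatenate([sim.reshape(-1), reg])

    def rmatvec(w: np.ndarray) -> np.ndarray:
        w1 = w[:m_data].reshape(template.values.shape)
        if wspec.corrected:
            w1 = _apply_weight_array(w1, wspec)  # S is symmetric
        sino_w = Sinogram(w1, template.ring, template.time_axis, ("weighted",))
        out = adjoint_apply(sino_w, spec).values.reshape(-1)
        if with_reg:
            img_w = SourceImage(w[m_data:].reshape(grid.shape), grid)
            out = out + sqrt_a * laplacian_apply(img_w).values.reshape(-1)
        return out

    return scipy.sparse.linalg.LinearOperator(
        (m, n), matvec=matvec, rmatvec=rmatvec, dtype=float
    )


def _lsqr_once(
    op: scipy.sparse.linalg.LinearOperator,
    b: np.ndarray,
    config: ReconConfig,
    iter_lim: int,
):
    return scipy.sparse.linalg.lsqr(
        op,
        b,
        atol=config.rel_tol,
        btol=config.rel_tol,
        conlim=0.0,
        iter_lim=iter_lim,
    )


def reconstruct_lsqr(
    sino: Sinogram, config: ReconConfig, history: bool = False
) -> tuple[SourceImage, ConvergenceLog]:
    """Matrix-free LSQR solve of the (weighted, regularized) least squares.

    Minimizes ``||S (M h - p)||^2 + alpha ||L h||^2`` (corrected) or the
    unweighted analogue via LSQR on the stacked operator, stopping at
    relative tolerance ``rel_tol`` or ``max_iters``.  Deterministic for
    fixed inputs.  With ``history=True`` the convergence log records every
    iterate (obtained by re-running the deterministic solve at increasing
    iteration limits — intended for small diagnostic instances).
    """
    if config.algorithm != "LSQR":
        raise ValueError("config.algorithm must be 'LSQR'")
    spec = config.operator_spec
    if sino.ring != spec.ring or sino.time_axis != spec.time_axis:
        raise ValueError("sinogram geometry does not match operator spec")
    data = sino.values
    if config.weight.corrected:
        data = _apply_weight_array(data, config.weight)
    n = spec.grid.n_pixels
    with_reg = config.reg_weight > 0
    b = data.reshape(-1)
    if with_reg:
        b = np.concatenate([b, np.zeros(n)])
    op = _stacked_operator(config, sino)

    if history:
        its, res, sol = [], [], []
        istop_last = 0
        for k in range(1, config.max_iters + 1):
            xk, istop_k, itn, r1norm = _lsqr_once(op, b, config, k)[:4]
            its.append(itn)
            res.append(r1norm)
            sol.append(float(np.linalg.norm(xk)))
            istop_last = istop_k
            x = xk
            if itn < k:  # converged before the limit
                break
        log = ConvergenceLog(
            np.asarray(its), np.asarray(res), np.asarray(sol), istop_last
        )
    else:
        x, istop, itn, r1norm = _lsqr_once(op, b, config, config.max_iters)[:4]
        log = ConvergenceLog(
            np.asarray([itn]),
            np.asarray([r1norm]),
            np.asarray([float(np.linalg.norm(x))]),
            istop,
        )
    if not np.all(np.isfinite(x)):
        raise RuntimeError(
            f"LSQR produced non-finite iterates (istop={log.istop}, "
            f"iterations={log.iterations[-1]})"
        )
    return SourceImage(x.reshape(spec.grid.shape), spec.grid), log


def pad_sinogram(sino: Sinogram, n_lead_zeros: int) -> Sinogram:
    """Prepend zero time columns, shifting ``t0`` back by ``n * dt``.

    Accounts for acquisition dead time (electromagnetic delay, headwave)
    in experimental data whose trigger does not coincide with ``t = 0``.
    """
    if n_lead_zeros < 0:
        raise ValueError("n_lead_zeros must be >= 0")
    if n_lead_zeros == 0:
        return sino
    ta = sino.time_axis
    new_ta = TimeAxis(
        t0=ta.t0 - n_lead_zeros * ta.dt,
        dt=ta.dt,
        n_samples=ta.n_samples + n_lead_zeros,
    )
    vals = np.concatenate(
        [np.zeros((sino.n_detectors, n_lead_zeros)), sino.values], axis=1
    )
    return Sinogram(vals, sino.ring, new_ta, sino.provenance)


def crop_sinogram(sino: Sinogram, n_lead: int) -> Sinogram:
    """Drop the first ``n_lead`` time columns (inverse of :func:`pad_sinogram`)."""
    if n_lead < 0 or n_lead >= sino.n_samples:
        raise ValueError("n_lead out of range")
    if n_lead == 0:
        return sino
    ta = sino.time_axis
    new_ta = TimeAxis(
        t0=ta.t0 + n_lead * ta.dt, dt=ta.dt, n_samples=ta.n_samples - n_lead
    )
    return Sinogram(sino.values[:, n_lead:], sino.ring, new_ta, sino.provenance)


def sweep_alpha(
    sino: Sinogram,
    config: ReconConfig,
    reference: SourceImage,
    alphas: np.ndarray,
) -> tuple[float, list[dict]]:
    """Pick the Laplacian weight maximizing correlation with a reference.

    Runs the configured LSQR solve at each candidate ``alpha`` and scores
    the Pearson correlation against ``reference`` (typically the known
    phantom on a held-out realization).  Returns the best alpha and the
    full score table for the run log.
    """
    from .metrics import pearson_rho

    rows = []
    for a in np.asarray(alphas, dtype=float):
        cfg = replace(config, reg_weight=float(a))
        img, log = reconstruct_lsqr(sino, cfg)
        rows.append(
            {
                "alpha": float(a),
                "rho": pearson_rho(img, reference),
                "iterations": int(log.iterations[-1]),
            }
        )
    best = max(rows, key=lambda r: r["rho"])
    return best["alpha"], rows
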