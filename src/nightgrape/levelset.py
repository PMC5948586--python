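"""Improved two-region Chan-Vese level set with coarse-to-fine pyramid.

The segmenter evolves a scalar field phi over the image grid; its sign
partitions the pixels into fruit (phi > 0) and background.  The energy is
the piecewise-constant two-region functional

    E = mu * L(C) + nu * S_o + lambda_o * sum_in (I - c_o)^2
                             + lambda_b * sum_out (I - c_b)^2

with c_o, c_b the current region means and L(C) a discrete contour length.
Instead of a signed distance function, phi is initialized as a two-valued
step (rho_u below a boundary row, rho_d above it) and is never
re-initialized during evolution.  The explicit update multiplies the
gradient-flow velocity by a smoothed Dirac factor delta_eps(phi); the two
rows adjacent to the initialization boundary receive an extra constant
kick +/- (u/h) * sign(rho_u - rho_d) that starts the interface moving.

For speed the image is first segmented at a 6x reduced resolution, the
coarse mask is upsampled, phi is rebuilt from it as a +/-|rho| step, and a
short full-resolution refinement finishes the contour.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .preprocessing import ChannelImage, InvalidInputError, PipelineConfig, downsample_channel

#: intensity scale the evolution is computed on; weights quoted on the raw
#: 0-255 scale are divided by INTENSITY_SCALE**2 internally so the velocity
#: is O(1) and the explicit step is stable without re-initialization.
INTENSITY_SCALE = 255.0


class NumericalDivergenceError(RuntimeError):
    """Raised when the explicit update produces non-finite values."""

    def __init__(self, iteration: int):
        super().__init__(f"level-set evolution diverged at iteration {iteration}")
        self.iteration = iteration


@dataclass(frozen=True)
class CvParams:
    """Weights and numerics of the improved Chan-Vese evolution.

    All energy weights are quoted on the raw 0-255 intensity scale.
    ``rho_u`` and ``rho_d`` are the two initialization constants; their
    product must be negative.  ``y0`` is the initialization boundary row
    (``None`` means H // 2).  ``u_param`` is the magnitude of the constant
    kick applied to rows j0 and j0 - 1; it must stay well below 1 on the
    unit velocity scale or it permanently overrides the image force on
    those rows.
    """

    mu: float = 0.01 * 255.0**2
    nu: float = 0.08 * 255.0**2
    lambda_o: float = 1.0
    lambda_b: float = 1.0
    dt: float = 5.0
    h: float = 1.0
    u_param: float = 0.05
    rho_u: float = 1.0
    rho_d: float = -1.0
    y0: int | None = None
    eps: float = 1.0
    max_iter: int = 800
    refine_max_iter: int = 80
    min_iter: int = 50
    patience: int = 60
    change_tol: float = 1e-4
    orient_bright: bool = True

    def __post_init__(self) -> None:
        if self.rho_u * self.rho_d >= 0:
            raise InvalidInputError("rho_u * rho_d must be negative")
        if self.dt <= 0 or self.eps <= 0 or self.h <= 0:
            raise InvalidInputError("dt, eps and h must be positive")
        if self.max_iter < 1:
            raise InvalidInputError("max_iter must be at least 1")
        if min(self.mu, self.nu, self.lambda_o, self.lambda_b, self.u_param) < 0:
            raise InvalidInputError("energy weights and u_param must be nonnegative")


@dataclass
class LevelSetField:
    """State of the evolving level set.

    ``boundary_row`` is j0 of the step initialization (None once phi is
    rebuilt from a mask, in which case the boundary-row kick is inactive).
    """

    phi: np.ndarray
    iteration: int = 0
    boundary_row: int | None = None
    energy_trace: list = field(default_factory=list)
    degenerate: bool = False

    def copy(self) -> "LevelSetField":
        return LevelSetField(
            self.phi.copy(),
            self.iteration,
            self.boundary_row,
            list(self.energy_trace),
            self.degenerate,
        )


@dataclass
class BinaryMask:
    """Fruit/background labeling (True = fruit)."""

    labels: np.ndarray
    connectivity: int = 8

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=bool)
        if self.labels.ndim != 2:
            raise InvalidInputError("mask must be 2-D")
        if self.connectivity not in (4, 8):
            raise InvalidInputError("connectivity must be 4 or 8")

    @property
    def count(self) -> int:
        return int(self.labels.sum())


@dataclass
class SegmentResult:
    """Mask plus the converged field and iteration count."""

    mask: BinaryMask
    field: LevelSetField
    iterations: int
    degenerate: bool = False


def initialize_phi(shape: tuple[int, int], params: CvParams) -> LevelSetField:
    """Two-valued step initialization: rho_u on rows y >= y0, rho_d above."""
    H, W = shape
    if H < 2 or W < 2:
        raise InvalidInputError("grid must be at least 2x2")
    y0 = params.y0 if params.y0 is not None else H // 2
    if not (0 <= y0 <= H - 1):
        raise InvalidInputError(f"y0={y0} outside rows [0, {H - 1}]")
    phi = np.empty((H, W), dtype=np.float64)
    phi[y0:, :] = params.rho_u
    phi[:y0, :] = params.rho_d
    return LevelSetField(phi, iteration=0, boundary_row=y0)


def region_means(values: np.ndarray, phi: np.ndarray) -> tuple[float, float, bool]:
    """Means of the phi>0 and phi<=0 regions; empty region -> mean 0, flagged."""
    inside = phi > 0
    n_in = int(inside.sum())
    n_out = inside.size - n_in
    degenerate = n_in == 0 or n_out == 0
    v = values.astype(np.float64)
    c_o = float(v[inside].mean()) if n_in else 0.0
    c_b = float(v[~inside].mean()) if n_out else 0.0
    return c_o, c_b, degenerate


def contour_length(phi: np.ndarray, h: float = 1.0) -> float:
    """Discrete perimeter: 4-neighbor sign-change pairs times grid step."""
    inside = phi > 0
    changes = np.count_nonzero(inside[1:, :] != inside[:-1, :])
    changes += np.count_nonzero(inside[:, 1:] != inside[:, :-1])
    return float(changes) * h


def cv_energy(
    channel: ChannelImage, field_: LevelSetField, params: CvParams
) -> float:
    """Evaluate the two-region energy of the current partition."""
    phi = field_.phi
    if phi.shape != channel.shape:
        raise InvalidInputError("field and channel dimensions differ")
    v = channel.values.astype(np.float64)
    c_o, c_b, degenerate = region_means(v, phi)
    if degenerate:
        field_.degenerate = True
    inside = phi > 0
    fit_in = float(((v - c_o) ** 2)[inside].sum()) if inside.any() else 0.0
    fit_out = float(((v - c_b) ** 2)[~inside].sum()) if (~inside).any() else 0.0
    area = float(inside.sum()) * params.h**2
    return (
        params.mu * contour_length(phi, params.h)
        + params.nu * area
        + params.lambda_o * fit_in
        + params.lambda_b * fit_out
    )


def _curvature(phi: np.ndarray, h: float) -> np.ndarray:
    """Curvature of the level lines of phi, div(grad phi / |grad phi|)."""
    py, px = np.gradient(phi, h)
    pyy, pyx = np.gradient(py, h)
    _, pxx = np.gradient(px, h)
    num = pxx * py**2 - 2.0 * px * py * pyx + pyy * px**2
    den = (px**2 + py**2) ** 1.5 + 1e-8
    return num / den


def dirac(phi: np.ndarray, eps: float) -> np.ndarray:
    """Smoothed Dirac delta, eps / (pi (phi^2 + eps^2))."""
    return eps / (np.pi * (phi**2 + eps**2))


def cv_velocity(
    values: np.ndarray, phi: np.ndarray, params: CvParams
) -> np.ndarray:
    """Gradient-flow velocity on the unit intensity scale.

    R = mu' kappa(phi) - nu' - lambda_o (I' - c_o')^2 + lambda_b (I' - c_b')^2
    with primes denoting division by the intensity scale (squared for the
    energy weights).
    """
    s = INTENSITY_SCALE
    v = values.astype(np.float64) / s
    c_o, c_b, _ = region_means(values, phi)
    c_o /= s
    c_b /= s
    kappa = _curvature(phi, params.h)
    return (
        (params.mu / s**2) * kappa
        - params.nu / s**2
        - params.lambda_o * (v - c_o) ** 2
        + params.lambda_b * (v - c_b) ** 2
    )


def cv_evolve(
    channel: ChannelImage, field_: LevelSetField, params: CvParams
) -> LevelSetField:
    """One explicit update step of the improved evolution.

    phi^{n+1} = phi^n + dt * delta_eps(phi^n) * V, where V equals the
    gradient-flow velocity R away from the initialization boundary and
    R -/+ (u/h) sign(rho_u - rho_d) on rows j0 / j0-1.
    """
    phi = field_.phi
    if phi.shape != channel.shape:
        raise InvalidInputError("field and channel dimensions differ")
    with np.errstate(invalid="ignore", over="ignore"):
        V = cv_velocity(channel.values, phi, params)
        j0 = field_.boundary_row
        if j0 is not None and params.u_param > 0.0:
            kick = (params.u_param / params.h) * np.sign(params.rho_u - params.rho_d)
            V = V.copy()
            V[j0, :] -= kick
            if j0 - 1 >= 0:
                V[j0 - 1, :] += kick
        delta = dirac(phi, params.eps)
        # where delta underflows to zero the update vanishes identically,
        # even if the velocity is not representable there (huge phi values)
        force = np.where(delta == 0.0, 0.0, params.dt * delta * V)
    phi_new = phi + force
    if not np.all(np.isfinite(phi_new)):
        raise NumericalDivergenceError(field_.iteration + 1)
    # keep phi a bounded step field: without re-initialization phi would
    # grow wherever the force is consistent, the Dirac factor would
    # collapse, and late corrections (after the region means have moved)
    # would stall.  The bound never pulls in values already beyond it, so
    # a vanishing update leaves the field untouched exactly.
    cap = np.maximum(max(abs(params.rho_u), abs(params.rho_d)), np.abs(phi))
    phi_new = np.clip(phi_new, -cap, cap)
    out = field_.copy()
    out.phi = phi_new
    out.iteration = field_.iteration + 1
    return out


def _orient(field_: LevelSetField, values: np.ndarray) -> LevelSetField:
    """Flip the sign of phi so the phi>0 region is the brighter one."""
    inside = field_.phi > 0
    if inside.any() and (~inside).any():
        if values[inside].mean() < values[~inside].mean():
            field_.phi = -field_.phi
    return field_


def _run(
    channel: ChannelImage,
    field_: LevelSetField,
    params: CvParams,
    max_iter: int,
    trace_energy: bool,
) -> tuple[LevelSetField, int]:
    iters = 0
    quiet = 0
    for _ in range(max_iter):
        prev_sign = field_.phi > 0
        field_ = cv_evolve(channel, field_, params)
        iters += 1
        if trace_energy:
            field_.energy_trace.append(cv_energy(channel, field_, params))
        changed = np.count_nonzero((field_.phi > 0) != prev_sign)
        # burn-in + patience: from the flat step initialization the region
        # means start nearly equal, so early steps flip almost nothing and
        # the drainage phase has isolated flip-free steps; stop only once
        # the sign-change fraction stays below tolerance for several
        # consecutive steps after the burn-in
        if changed / field_.phi.size < params.change_tol:
            quiet += 1
            if iters >= params.min_iter and quiet >= params.patience:
                break
        else:
            quiet = 0
    return field_, iters


def segment(
    channel: ChannelImage,
    params: CvParams | None = None,
    max_iter: int | None = None,
    trace_energy: bool = False,
    full_output: bool = False,
):
    """Segment a channel by evolving the step-initialized level set.

    Iterates until the fraction of pixels whose sign of phi changed in a
    step drops below ``change_tol``, or ``max_iter`` steps.  The returned
    mask is {phi > 0}; with ``orient_bright`` (default) the sign of phi is
    flipped after convergence if the phi>0 region came out darker, so fruit
    — the bright region of the rotated R channel — is the foreground.

    A zero-contrast channel cannot define two regions: the result is an
    all-false mask flagged degenerate.
    """
    params = params or CvParams()
    n_iter = max_iter if max_iter is not None else params.max_iter
    values = channel.values
    if values.max() == values.min():
        phi = np.full(channel.shape, -abs(params.rho_u), dtype=np.float64)
        f = LevelSetField(phi, degenerate=True)
        res = SegmentResult(BinaryMask(phi > 0), f, 0, degenerate=True)
        return res if full_output else res.mask
    field_ = initialize_phi(channel.shape, params)
    if trace_energy:
        field_.energy_trace.append(cv_energy(channel, field_, params))
    field_, iters = _run_phased(channel, field_, params, n_iter, trace_energy)
    if params.orient_bright:
        field_ = _orient(field_, values)
    res = SegmentResult(BinaryMask(field_.phi > 0), field_, iters)
    return res if full_output else res.mask


def _run_phased(
    channel: ChannelImage,
    field_: LevelSetField,
    params: CvParams,
    max_iter: int,
    trace_energy: bool = False,
) -> tuple[LevelSetField, int]:
    """Fidelity-only evolution, then continuation with the area penalty.

    From a balanced interface the region means start nearly equal, so the
    constant area force would drain phi uniformly toward the empty region
    before the fidelity terms can differentiate the partition.  Phase one
    therefore evolves with nu = 0 until the partition settles; phase two
    switches the area penalty on, which detaches weakly fitting dim
    structures (foliage) without collapsing the fruit region.

    The area term penalizes the phi>0 region only, so phase two is
    meaningful only with the object on the positive side; when
    ``orient_bright`` is set the field is re-oriented between the phases.
    """
    field_, iters = _run(
        channel, field_, replace(params, nu=0.0), max_iter, trace_energy
    )
    if params.nu > 0.0:
        if params.orient_bright:
            field_ = _orient(field_, channel.values)
        field_, extra = _run(channel, field_, params, max_iter, trace_energy)
        iters += extra
    return field_, iters


def phi_from_mask(mask: BinaryMask, rho: float) -> LevelSetField:
    """Rebuild phi as a +/-|rho| step from a mask (no boundary-row kick)."""
    phi = np.where(mask.labels, abs(rho), -abs(rho)).astype(np.float64)
    return LevelSetField(phi, iteration=0, boundary_row=None)


def upsample_mask(mask: BinaryMask, factor: int) -> BinaryMask:
    """Nearest-neighbor (block) upsampling of a mask by an integer factor."""
    return BinaryMask(np.kron(mask.labels, np.ones((factor, factor), dtype=bool)))


def segment_pyramid(
    channel: ChannelImage,
    params: CvParams | None = None,
    config: PipelineConfig | None = None,
    full_output: bool = False,
):
    """Coarse-to-fine segmentation.

    The channel is downsampled to the coarse resolution, segmented to
    convergence, the coarse mask is block-upsampled back to working
    resolution, phi is rebuilt from it as a +/-|rho| step, and a short
    full-resolution refinement produces the final mask.
    """
    params = params or CvParams()
    config = config or PipelineConfig()
    sw, sh = config.standard_size
    if channel.shape != (sh, sw):
        raise InvalidInputError(
            f"pyramid segmentation expects a {sw}x{sh} channel, got "
            f"{channel.shape[1]}x{channel.shape[0]}"
        )
    coarse = downsample_channel(channel, config.coarse_size)
    coarse_res = segment(coarse, params, full_output=True)
    if coarse_res.degenerate:
        mask = BinaryMask(np.zeros((sh, sw), dtype=bool))
        res = SegmentResult(mask, coarse_res.field, 0, degenerate=True)
        return res if full_output else res.mask
    up = upsample_mask(coarse_res.mask, config.pyramid_factor)
    field_ = phi_from_mask(up, params.rho_u)
    field_, iters = _run_phased(channel, field_, params, params.refine_max_iter)
    if params.orient_bright:
        field_ = _orient(field_, channel.values)
    res = SegmentResult(BinaryMask(field_.phi > 0), field_, iters)
    res.field.energy_trace = coarse_res.field.energy_trace
    if full_output:
        res.coarse_iterations = coarse_res.iterations  # type: ignore[attr-defined]
        res.coarse_mask = coarse_res.mask  # type: ignore[attr-defined]
        return res
    return res.mask
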