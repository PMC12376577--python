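"""Displacement and strain computation from image frame pairs.

Cardiac strains are measured between end-diastole and end-systole by
registering the two frames, converting the recovered displacement field
into deformation gradients, and rotating the resulting Green-Lagrange
strain tensor into the local circumferential/radial/longitudinal (CRL)
frame of the heart wall.

Registration minimizes the diffusion-regularized cost

    Psi(c, u) = ||F - M o c||^2 / sigma_i^2
              + ||u - c||^2     / sigma_x^2
              + ||grad u||^2    / sigma_T^2

over a non-parametric correspondence ``c`` and a smooth parametric
displacement ``u``, by a demons-style alternating scheme: an intensity
force update of ``c`` followed by Gaussian smoothing toward ``u``.  The
scheme is monotone on accepted iterations — the cost never increases.

Kinematics follow finite-strain theory: incremental deformation
gradients ``F_i = I + du/dX`` between consecutive frames are composed by
pointwise matrix product ``F = F_n ... F_2 F_1`` (latest increment
leftmost), and ``E = (F^T F - I) / 2``.  Two-dimensional slices are
embedded in 3-D with zero out-of-plane displacement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage


@dataclass
class RegistrationParams:
    """Weights and stopping rules of the registration cost.

    sigma_i scales the intensity-mismatch term, sigma_x the coupling
    between correspondence and displacement, sigma_t the smoothness
    penalty on the displacement gradient.
    """

    sigma_i: float = 1.0
    sigma_x: float = 1.0
    sigma_t: float = 2.0
    max_iterations: int = 200
    tol: float = 1e-6

    def __post_init__(self):
        if min(self.sigma_i, self.sigma_x, self.sigma_t) <= 0:
            raise ValueError("all regularization weights must be positive")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")


@dataclass
class RegistrationResult:
    """Displacement field (pixel units, components (u_y, u_x) stacked last),
    final correspondence, per-iteration cost, and a convergence flag."""

    displacement: np.ndarray
    correspondence: np.ndarray
    costs: list
    converged: bool


def _warp(moving: np.ndarray, disp: np.ndarray) -> np.ndarray:
    """Sample ``moving`` at grid + disp (M o c); linear interpolation."""
    h, w = moving.shape
    gy, gx = np.mgrid[0:h, 0:w].astype(np.float64)
    coords = np.stack([gy + disp[..., 0], gx + disp[..., 1]])
    return ndimage.map_coordinates(moving, coords, order=1, mode="nearest")


def registration_cost(fixed, moving, c, u, params: RegistrationParams) -> float:
    """Evaluate Psi(c, u) (mean-per-pixel squared norms)."""
    n = fixed.size
    resid = fixed - _warp(moving, c)
    sim = np.sum(resid ** 2) / n
    dist = np.sum((u - c) ** 2) / n
    gy0 = np.gradient(u[..., 0], axis=0)
    gy1 = np.gradient(u[..., 0], axis=1)
    gx0 = np.gradient(u[..., 1], axis=0)
    gx1 = np.gradient(u[..., 1], axis=1)
    smooth = np.sum(gy0 ** 2 + gy1 ** 2 + gx0 ** 2 + gx1 ** 2) / n
    return (sim / params.sigma_i ** 2 + dist / params.sigma_x ** 2
            + smooth / params.sigma_t ** 2)


def register(fixed: np.ndarray, moving: np.ndarray,
             params: RegistrationParams | None = None) -> RegistrationResult:
    """Estimate the displacement field aligning ``moving`` onto ``fixed``.

    Demons-style alternating minimization of the registration cost: the
    correspondence update pushes along the warped-image gradient scaled by
    the intensity residual (force magnitude limited by the sigma_i/sigma_x
    ratio), and the displacement update smooths the correspondence with a
    Gaussian of width sigma_t / sigma_x.  Iterations that would increase
    the cost are rejected and terminate the loop.
    """
    params = params or RegistrationParams()
    fixed = np.asarray(fixed, dtype=np.float64)
    moving = np.asarray(moving, dtype=np.float64)
    if fixed.shape != moving.shape:
        raise ValueError("fixed and moving frames must share a shape")
    if not (np.all(np.isfinite(fixed)) and np.all(np.isfinite(moving))):
        raise ValueError("image intensities must be finite")

    h, w = fixed.shape
    u = np.zeros((h, w, 2))
    c = np.zeros((h, w, 2))
    smooth_sigma = params.sigma_t / params.sigma_x
    alpha = params.sigma_i / params.sigma_x  # demons force normalization

    cost = registration_cost(fixed, moving, c, u, params)
    costs = [cost]
    converged = False
    for _ in range(params.max_iterations):
        step = 1.0
        warped = _warp(moving, u)
        resid = fixed - warped
        gy, gx = np.gradient(warped)
        denom = gy ** 2 + gx ** 2 + (alpha ** 2) * resid ** 2
        with np.errstate(divide="ignore", invalid="ignore"):
            scale = np.where(denom > 1e-12, resid / denom, 0.0)
        force = np.stack([scale * gy, scale * gx], axis=-1)
        # damped step: halve until the full cost decreases (monotone descent)
        accepted = False
        while step >= 1e-4:
            c_new = u + step * force
            u_new = np.stack([
                ndimage.gaussian_filter(c_new[..., 0], smooth_sigma),
                ndimage.gaussian_filter(c_new[..., 1], smooth_sigma),
            ], axis=-1)
            new_cost = registration_cost(fixed, moving, c_new, u_new, params)
            if new_cost <= cost:
                accepted = True
                break
            step *= 0.5
        if not accepted:
            converged = True
            break
        c, u = c_new, u_new
        rel = (cost - new_cost) / max(cost, 1e-30)
        costs.append(new_cost)
        cost = new_cost
        if rel < params.tol:
            converged = True
            break
    return RegistrationResult(displacement=u, correspondence=c,
                              costs=costs, converged=converged)


# ---------------------------------------------------------------------------
# deformation gradients and strain

def incremental_gradient(u: np.ndarray) -> np.ndarray:
    """Incremental deformation gradient F_i = I + du/dX per grid point.

    ``u`` is (..., H, W, 2) for 2-D fields ((u_y, u_x) order, pixel units)
    or (D, H, W, 3) for 3-D.  Spatial derivatives use central differences
    in the interior and one-sided differences at borders.  2-D fields are
    embedded in 3-D with F_i[2, 2] = 1 and zero out-of-plane coupling.
    Returns an array of 3x3 tensors with shape grid + (3, 3).
    """
    u = np.asarray(u, dtype=np.float64)
    if u.ndim == 3 and u.shape[-1] == 2:
        h, w = u.shape[:2]
        F = np.zeros((h, w, 3, 3))
        F[..., 0, 0] = F[..., 1, 1] = F[..., 2, 2] = 1.0
        # rows: displacement component; cols: differentiation axis
        F[..., 0, 0] += np.gradient(u[..., 0], axis=0)
        F[..., 0, 1] += np.gradient(u[..., 0], axis=1)
        F[..., 1, 0] += np.gradient(u[..., 1], axis=0)
        F[..., 1, 1] += np.gradient(u[..., 1], axis=1)
        return F
    if u.ndim == 4 and u.shape[-1] == 3:
        grid = u.shape[:3]
        F = np.zeros(grid + (3, 3))
        for i in range(3):
            F[..., i, i] = 1.0
        for comp in range(3):
            grads = np.gradient(u[..., comp], axis=(0, 1, 2))
            for ax in range(3):
                F[..., comp, ax] += grads[ax]
        return F
    raise ValueError("u must be (H, W, 2) or (D, H, W, 3)")


def propagate(increments) -> np.ndarray:
    """Compose incremental deformation gradients into the total F.

    Pointwise ordered product F = F_n ... F_2 F_1: the first increment in
    the list is applied first (rightmost factor), the latest last.
    """
    increments = list(increments)
    if not increments:
        raise ValueError("at least one increment is required")
    total = np.asarray(increments[0], dtype=np.float64)
    for inc in increments[1:]:
        if inc.shape != total.shape:
            raise ValueError("all increments must share a grid")
        total = np.asarray(inc) @ total
    return total


def green_lagrange(F: np.ndarray) -> np.ndarray:
    """Green-Lagrange strain E = (F^T F - I) / 2, symmetric by construction."""
    F = np.asarray(F, dtype=np.float64)
    eye = np.eye(F.shape[-1])
    return 0.5 * (np.swapaxes(F, -1, -2) @ F - eye)


def build_crl_basis(center, point, long_axis=(0.0, 0.0, 1.0)) -> np.ndarray:
    """Local CRL basis at a point of a short-axis slice.

    Rows of the returned 3x3 matrix Q are the circumferential, radial and
    longitudinal unit vectors: radial points in-plane from the slice
    center to the point, longitudinal along the long axis, circumferential
    completes the right-handed triad (radial x longitudinal, so that
    det Q = +1 with the (C, R, L) row order).
    """
    center = np.asarray(center, dtype=np.float64)
    point = np.asarray(point, dtype=np.float64)
    if center.shape == (2,):
        center = np.append(center, 0.0)
    if point.shape == (2,):
        point = np.append(point, 0.0)
    ell = np.asarray(long_axis, dtype=np.float64)
    ell = ell / np.linalg.norm(ell)
    radial = point - center
    radial = radial - np.dot(radial, ell) * ell  # in-plane projection
    norm = np.linalg.norm(radial)
    if norm < 1e-12:
        raise ValueError("point coincides with the slice center")
    radial = radial / norm
    circ = np.cross(radial, ell)
    return np.stack([circ, radial, ell])


def save_fields_npz(path, **fields):
    """Write image frames / displacement fields / strain tensors to NPZ."""
    np.savez(path, **{k: np.asarray(v) for k, v in fields.items()})


def load_fields_npz(path) -> dict:
    with np.load(path) as data:
        return {k: data[k] for k in data.files}


def params_to_json(params: RegistrationParams) -> str:
    import json
    from dataclasses import asdict
    return json.dumps(asdict(params))


def params_from_json(text: str) -> RegistrationParams:
    import json
    return RegistrationParams(**json.loads(text))


def to_crl(E: np.ndarray, Q: np.ndarray, atol: float = 1e-8):
    """Rotate a Cartesian strain tensor into the CRL frame: E_crl = Q E Q^T.

    Returns ``(E_crl, components)`` where ``components`` maps 'CC', 'RR',
    'LL', 'CR', 'CL', 'RL' to the named entries.  Raises if E is not
    symmetric within ``atol``.
    """
    E = np.asarray(E, dtype=np.float64)
    if not np.allclose(E, np.swapaxes(E, -1, -2), atol=atol):
        raise ValueError("strain tensor must be symmetric")
    E_crl = Q @ E @ np.swapaxes(Q, -1, -2)
    components = {
        "CC": E_crl[..., 0, 0], "RR": E_crl[..., 1, 1], "LL": E_crl[..., 2, 2],
        "CR": E_crl[..., 0, 1], "CL": E_crl[..., 0, 2], "RL": E_crl[..., 1, 2],
    }
    return E_crl, components
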