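"""Synthetic left-ventricular strain phantoms with known infarct masks.

A healthy left ventricle contracts at end-systole: circumferential and
longitudinal strains are negative, radial strain positive.  A chronic
infarct is stiff, poorly contracting tissue, so within the scar all three
strain magnitudes collapse toward zero, with a partially contracting
border zone around it.  The generator emulates exactly that statistical
structure on the four-level bullseye grid used downstream: a baseline
contraction pattern, an infarct patch of prescribed area fraction placed
at a prescribed location, magnitude attenuation that increases with scar
stiffness, a smooth angular border zone, and additive measurement noise.

Infarct location and size are drawn by Latin hypercube sampling so that a
library of phantoms covers the parameter space uniformly: infarct size
5-60% of the LV, scar stiffness within +/-30% of its mean.

A parametric low-to-high fidelity shift (gain/offset plus a bounded
nonlinear distortion and extra noise) mimics the systematic gap between
abundant simulated data and scarce subject-specific data, giving the
multi-fidelity correction heads a learnable target.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.stats import qmc

from .bullseye import BullseyeLayout, LEVEL_NAMES, rasterize_patch

#: Baseline end-systolic strain per component (E_CC, E_RR, E_LL),
#: dimensionless Green-Lagrange strain.
DEFAULT_BASELINE = (-0.15, 0.35, -0.12)

#: Attenuation steepness: scar strain magnitude is multiplied by
#: 1 / (1 + stiffness_scale * ATTENUATION_K).
ATTENUATION_K = 4.0

#: Angular width of the smooth border zone (radians); ~15 degrees.
BORDER_ZONE = np.deg2rad(15.0)

DEFAULT_BOUNDS = {
    "infarct_fraction": (0.05, 0.60),
    "stiffness_scale": (0.7, 1.3),
}


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic infarcted ventricle.

    ``infarct_center`` is (level index 0-3 in base/mid/apical/apex order,
    angle in [0, 2pi)).  ``infarct_fraction`` is the scar's share of total
    LV (disc) area; ``stiffness_scale`` multiplies the mean scar stiffness.
    A fraction of exactly 0 is accepted as a healthy-control override.
    """

    infarct_center: tuple
    infarct_fraction: float
    stiffness_scale: float
    noise_sd: float = 0.01
    seed: int = 0
    fidelity: str = "low"

    def __post_init__(self):
        level, angle = self.infarct_center
        if level not in (0, 1, 2, 3):
            raise ValueError(f"level index must be 0..3, got {level}")
        if not (0.0 <= angle < 2 * np.pi):
            raise ValueError("infarct angle must lie in [0, 2pi)")
        if self.infarct_fraction != 0.0 and not (0.05 <= self.infarct_fraction <= 0.60):
            raise ValueError("infarct_fraction must lie in [0.05, 0.60]")
        if not (0.7 <= self.stiffness_scale <= 1.3):
            raise ValueError("stiffness_scale must lie in [0.7, 1.3]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.fidelity not in ("low", "high"):
            raise ValueError("fidelity must be 'low' or 'high'")


@dataclass(frozen=True)
class StrainSliceSet:
    """CRL strain samples at the four short-axis levels.

    ``values`` has shape (4, n_theta, 3): levels in base/mid/apical/apex
    order, uniform angular samples over [0, 2pi), components (C, R, L).
    """

    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 3 or v.shape[0] != 4 or v.shape[2] != 3:
            raise ValueError("values must have shape (4, n_theta, 3)")
        if not np.all(np.isfinite(v)):
            raise ValueError("strain values must be finite")
        object.__setattr__(self, "values", v)

    @property
    def n_theta(self) -> int:
        return self.values.shape[1]

    @property
    def angles(self) -> np.ndarray:
        return np.linspace(0.0, 2 * np.pi, self.n_theta, endpoint=False)

    @property
    def levels(self):
        return dict(zip(LEVEL_NAMES, self.values))


@dataclass(frozen=True)
class FidelityShift:
    """Parametric low-to-high fidelity distortion.

    Pointwise: ``y = gain * x + offset + amplitude * g(x) + noise`` with
    ``g`` a bounded monotone distortion.  All-zero distortion parameters
    (gain 1, offset 0, amplitude 0, noise 0) give the exact identity.
    """

    linear_gain: float = 1.0
    linear_offset: float = 0.0
    nonlinear_amplitude: float = 0.0
    nonlinear_form: str = "tanh5"
    noise_sd: float = 0.0

    def g(self, x: np.ndarray) -> np.ndarray:
        if self.nonlinear_form == "tanh5":
            return np.tanh(5.0 * x)
        raise ValueError(f"unknown nonlinear_form {self.nonlinear_form!r}")


#: Default synthetic species gap used by multi-fidelity experiments.
DEFAULT_HF_SHIFT = FidelityShift(linear_gain=0.85, linear_offset=0.01,
                                 nonlinear_amplitude=0.05,
                                 nonlinear_form="tanh5", noise_sd=0.015)


def sample_phantom_specs(n: int, seed: int, bounds: dict | None = None,
                         noise_sd: float = 0.01, fidelity: str = "low"):
    """Draw ``n`` phantom specifications by Latin hypercube sampling.

    Four dimensions are stratified: infarct fraction, stiffness scale,
    infarct angle, and infarct level (continuous stratum mapped onto the
    four discrete levels).  Each continuous parameter lands exactly once
    in every 1/n-width stratum of its range; the draw is reproducible for
    a fixed seed.
    """
    if n < 1:
        raise ValueError("n must be a positive integer")
    bounds = {**DEFAULT_BOUNDS, **(bounds or {})}
    for key in ("infarct_fraction", "stiffness_scale"):
        lo, hi = bounds[key]
        dlo, dhi = DEFAULT_BOUNDS[key]
        if lo >= hi:
            raise ValueError(f"inverted bounds for {key}")
        if lo < dlo or hi > dhi:
            raise ValueError(f"bounds for {key} outside admissible range")

    sampler = qmc.LatinHypercube(d=4, seed=seed)
    u = sampler.random(n)  # columns: fraction, stiffness, angle, level
    f_lo, f_hi = bounds["infarct_fraction"]
    s_lo, s_hi = bounds["stiffness_scale"]
    fractions = f_lo + u[:, 0] * (f_hi - f_lo)
    stiffness = s_lo + u[:, 1] * (s_hi - s_lo)
    angles = u[:, 2] * 2 * np.pi
    levels = np.minimum((u[:, 3] * 4).astype(int), 3)

    specs = []
    for i in range(n):
        specs.append(PhantomSpec(
            infarct_center=(int(levels[i]), float(angles[i])),
            infarct_fraction=float(fractions[i]),
            stiffness_scale=float(stiffness[i]),
            noise_sd=noise_sd,
            seed=int((seed * 1_000_003 + i) % (2 ** 31)),
            fidelity=fidelity,
        ))
    return specs


def _infarct_patch(center_level: int, fraction: float, layout: BullseyeLayout):
    """Solve for the patch (levels, arc width) realizing an area fraction.

    The patch starts on the center level and its angular arc grows first;
    only when the full circle of the current levels cannot hold the target
    area is an adjacent level added (nearest level first, apex-ward on
    ties).  Returns (sorted level list, arc width in radians).
    """
    areas = layout.level_area_fractions()  # base..apex, sums to 1
    levels = [center_level]
    remaining = [l for l in range(4) if l != center_level]
    while True:
        covered = sum(areas[l] for l in levels)
        width = 2 * np.pi * fraction / covered
        if width <= 2 * np.pi or not remaining:
            return sorted(levels), min(width, 2 * np.pi)
        remaining.sort(key=lambda l: (abs(l - center_level), -l))
        levels.append(remaining.pop(0))


def generate_strain_field(spec: PhantomSpec, layout: BullseyeLayout | None = None,
                          n_theta: int = 128,
                          baseline: tuple = DEFAULT_BASELINE,
                          attenuation_k: float = ATTENUATION_K,
                          border_zone: float = BORDER_ZONE):
    """Generate the strain field and bullseye-coordinate infarct mask.

    The healthy baseline carries uniform contraction (E_CC < 0, E_RR > 0,
    E_LL < 0).  Inside the infarct patch strain magnitudes are multiplied
    by ``1 / (1 + stiffness_scale * attenuation_k)`` — a stiffer scar
    contracts less — with a cosine taper to healthy values over the border
    zone just outside the patch arc.  Gaussian noise of ``spec.noise_sd``
    strain units is added everywhere.

    Returns ``(StrainSliceSet, mask)`` where ``mask`` is the binary patch
    rasterized on ``layout`` (uint8, H x W).
    """
    layout = layout or BullseyeLayout()
    rng = np.random.default_rng(spec.seed)
    values = np.tile(np.asarray(baseline, dtype=np.float64), (4, n_theta, 1))

    if spec.infarct_fraction > 0.0:
        center_level, center_angle = spec.infarct_center
        levels, width = _infarct_patch(center_level, spec.infarct_fraction, layout)
        atten = 1.0 / (1.0 + spec.stiffness_scale * attenuation_k)
        angles = np.linspace(0.0, 2 * np.pi, n_theta, endpoint=False)
        # angular distance beyond the patch arc edge
        d = np.abs(np.mod(angles - center_angle + np.pi, 2 * np.pi) - np.pi)
        outside = np.clip(d - width / 2.0, 0.0, None)
        # weight 1 inside the arc, cosine-tapering to 0 across the border zone
        w = np.where(outside <= 0, 1.0,
                     np.where(outside >= border_zone, 0.0,
                              0.5 * (1 + np.cos(np.pi * outside / border_zone))))
        factor = 1.0 - (1.0 - atten) * w  # = atten inside, 1 far outside
        for lvl in levels:
            values[lvl] *= factor[:, None]
        mask = rasterize_patch(levels, center_angle, width, layout)
    else:
        mask = np.zeros((layout.resolution, layout.resolution), dtype=np.uint8)

    if spec.noise_sd > 0:
        values = values + rng.normal(0.0, spec.noise_sd, size=values.shape)
    return StrainSliceSet(values=values), mask


def apply_fidelity_shift(field: StrainSliceSet, shift: FidelityShift,
                         seed: int) -> StrainSliceSet:
    """Apply the pointwise fidelity distortion to every strain sample.

    Deterministic for a fixed seed; an identity shift returns values equal
    to the input.
    """
    x = field.values
    y = (shift.linear_gain * x + shift.linear_offset
         + shift.nonlinear_amplitude * shift.g(x))
    if shift.noise_sd > 0:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, shift.noise_sd, size=y.shape)
    return StrainSliceSet(values=y)
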