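"""AHA-style bullseye rendering of left-ventricular strain fields.

The left ventricle is summarized at four short-axis levels (base, mid,
apical, apex).  A bullseye map places the apex at the center of a disc and
the base at the rim; each level occupies one ring.  Strain values sampled
on an angular grid per level are painted into the ring with continuous
angular interpolation, producing one greyscale map per strain component
(circumferential, radial, longitudinal).  The three maps are stacked into
a 3-channel image that serves as network input.

Conventions (fixed so that masks, rotations and rendered images stay
aligned):

* angle 0 is at the +x axis ("anterior"), increasing counter-clockwise
  with the +y axis pointing up (row index decreasing);
* rings from the center outward are apex, apical, mid, base;
* pixels outside the inscribed circle (the region of interest) carry the
  background value 1.0 — white corners.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Short-axis level names, index 0..3.  Level i maps to ring ``3 - i``
#: counted from the disc center (apex innermost, base outermost).
LEVEL_NAMES = ("base", "mid", "apical", "apex")

#: Component order of strain channels: circumferential, radial, longitudinal.
COMPONENTS = ("C", "R", "L")

#: Default display windows (strain units) per component, chosen to bracket
#: physiological end-systolic ranges so absolute strain information is kept.
DEFAULT_WINDOWS = {"C": (-0.30, 0.10), "R": (-0.10, 0.60), "L": (-0.30, 0.10)}

BACKGROUND_VALUE = 1.0


@dataclass(frozen=True)
class BullseyeLayout:
    """Geometry of the bullseye disc.

    Parameters
    ----------
    resolution : int
        Pixels per image side; one of 128, 256, 512 (64 additionally
        accepted for reduced-scale experiments).
    ring_edges : tuple of float
        Five radii fractions partitioning [0, 1] into the apex disc plus
        three annuli (apex, apical, mid, base from center outward).
    """

    resolution: int = 128
    ring_edges: tuple = (0.0, 0.25, 0.5, 0.75, 1.0)
    angular_origin: float = 0.0
    counterclockwise: bool = True

    def __post_init__(self):
        if self.resolution not in (64, 128, 256, 512):
            raise ValueError(f"unsupported resolution {self.resolution}")
        e = np.asarray(self.ring_edges, dtype=float)
        if len(e) != 5 or e[0] != 0.0 or e[-1] != 1.0 or np.any(np.diff(e) <= 0):
            raise ValueError("ring_edges must be 5 strictly increasing radii from 0 to 1")

    # -- polar coordinate grids -------------------------------------------
    def polar_grid(self):
        """Per-pixel (radius, angle) with radius normalized to the inscribed circle.

        Returns ``(r, theta)`` arrays of shape (resolution, resolution);
        theta in [0, 2pi), measured counter-clockwise from the +x axis.
        """
        n = self.resolution
        c = (n - 1) / 2.0
        radius = n / 2.0
        i, j = np.mgrid[0:n, 0:n]
        x = (j - c) / radius
        y = (c - i) / radius
        r = np.hypot(x, y)
        theta = np.mod(np.arctan2(y, x) - self.angular_origin, 2 * np.pi)
        if not self.counterclockwise:
            theta = np.mod(2 * np.pi - theta, 2 * np.pi)
        return r, theta

    def ring_of_level(self, level: int) -> int:
        """Ring index (0 = innermost) occupied by short-axis level ``level``."""
        return 3 - level

    def level_area_fractions(self) -> np.ndarray:
        """Fraction of disc area occupied by each level (base..apex order)."""
        e = np.asarray(self.ring_edges)
        ring_areas = e[1:] ** 2 - e[:-1] ** 2  # apex..base from center out
        return ring_areas[::-1].copy()  # base..apex

    def level_index_map(self) -> np.ndarray:
        """Per-pixel level index (0..3); -1 outside the disc."""
        r, _ = self.polar_grid()
        ring = np.digitize(r, self.ring_edges[1:-1])  # 0..3 inside, 3+ outside
        level = 3 - ring
        level[r > 1.0] = -1
        return level


def circular_roi(layout: BullseyeLayout) -> np.ndarray:
    """Binary mask of the LV disc: 1 iff the pixel center lies within the
    circle inscribed in the image square (the white corners are excluded)."""
    r, _ = layout.polar_grid()
    return (r <= 1.0).astype(np.uint8)


def render_channel(slices, component: str, layout: BullseyeLayout | None = None,
                   window: tuple | None = None) -> np.ndarray:
    """Paint one strain component into a greyscale bullseye map.

    Each in-disc pixel takes the angularly interpolated strain of the ring
    its radius falls in, linearly windowed to [0, 1] by
    ``clip((value - lo) / (hi - lo), 0, 1)``.  Pixels outside the disc are
    set to the white background.

    Parameters
    ----------
    slices : StrainSliceSet
        Strain samples per level and angle.
    component : {'C', 'R', 'L'}
        Which strain direction to render.
    window : (lo, hi)
        Strain window in strain units; defaults per component.
    """
    layout = layout or BullseyeLayout()
    if component not in COMPONENTS:
        raise ValueError(f"unknown component {component!r}")
    if window is None:
        window = DEFAULT_WINDOWS[component]
    lo, hi = window
    if not (lo < hi):
        raise ValueError("degenerate window: require lo < hi")

    comp = COMPONENTS.index(component)
    values = slices.values  # (4, n_theta, 3)
    n_theta = values.shape[1]
    grid_angles = np.linspace(0.0, 2 * np.pi, n_theta, endpoint=False)

    r, theta = layout.polar_grid()
    level_map = layout.level_index_map()
    out = np.full(level_map.shape, BACKGROUND_VALUE, dtype=np.float64)

    # periodic linear interpolation per level
    xp = np.append(grid_angles, 2 * np.pi)
    for lvl in range(4):
        sel = level_map == lvl
        if not np.any(sel):
            continue
        fp = np.append(values[lvl, :, comp], values[lvl, 0, comp])
        v = np.interp(theta[sel], xp, fp)
        out[sel] = np.clip((v - lo) / (hi - lo), 0.0, 1.0)
    return out


def assemble_image(c_map: np.ndarray, r_map: np.ndarray, l_map: np.ndarray) -> np.ndarray:
    """Stack per-component greyscale maps into an H x W x 3 strain image.

    Channel order is (circumferential, radial, longitudinal); values are
    passed through unchanged.
    """
    if not (c_map.shape == r_map.shape == l_map.shape):
        raise ValueError("channel maps must share a shape")
    return np.stack([c_map, r_map, l_map], axis=-1)


def normalize(image: np.ndarray) -> np.ndarray:
    """Map pixel values to [0, 1].

    8-bit-scaled inputs (max > 1) are divided by 255; inputs already in
    [0, 1] pass through, making the operation idempotent.
    """
    image = np.asarray(image, dtype=np.float64)
    if not np.all(np.isfinite(image)):
        raise ValueError("image contains non-finite values")
    if image.max(initial=0.0) > 1.0:
        image = image / 255.0
    return np.clip(image, 0.0, 1.0)


def render_strain_image(slices, layout: BullseyeLayout | None = None,
                        windows: dict | None = None) -> np.ndarray:
    """Convenience: render all three components and assemble the image."""
    layout = layout or BullseyeLayout()
    windows = windows or DEFAULT_WINDOWS
    maps = [render_channel(slices, comp, layout, windows.get(comp))
            for comp in COMPONENTS]
    return assemble_image(*maps)


def rasterize_patch(levels, arc_center: float, arc_width: float,
                    layout: BullseyeLayout | None = None) -> np.ndarray:
    """Rasterize an infarct patch (set of levels x angular arc) to a binary mask."""
    layout = layout or BullseyeLayout()
    _, theta = layout.polar_grid()
    level_map = layout.level_index_map()
    in_level = np.isin(level_map, list(levels))
    d = np.abs(np.mod(theta - arc_center + np.pi, 2 * np.pi) - np.pi)
    in_arc = d <= arc_width / 2.0
    return (in_level & in_arc).astype(np.uint8)


def layout_to_json(layout: BullseyeLayout) -> str:
    """Serialize a layout to JSON."""
    import json
    return json.dumps({"resolution": layout.resolution,
                       "ring_edges": list(layout.ring_edges),
                       "angular_origin": layout.angular_origin,
                       "counterclockwise": layout.counterclockwise})


def layout_from_json(text: str) -> BullseyeLayout:
    """Deserialize a layout written by :func:`layout_to_json`."""
    import json
    data = json.loads(text)
    data["ring_edges"] = tuple(data["ring_edges"])
    return BullseyeLayout(**data)


def augment_rotations(dataset):
    """Fourfold rotation augmentation: originals plus 90/180/270 degrees.

    ``dataset`` is a sequence of (image, mask) pairs with square spatial
    grids; the same rotation is applied jointly to every image channel and
    to the mask, so labels stay aligned with their inputs.
    """
    out = []
    for image, mask in dataset:
        image = np.asarray(image)
        mask = np.asarray(mask)
        if image.shape[0] != image.shape[1] or mask.shape[0] != mask.shape[1]:
            raise ValueError("rotation augmentation requires square images")
        out.append((image, mask))
    for k in (1, 2, 3):
        for image, mask in list(out[: len(dataset)]):
            out.append((np.rot90(image, k, axes=(0, 1)).copy(),
                        np.rot90(mask, k, axes=(0, 1)).copy()))
    return out
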