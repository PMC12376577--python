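"""Dataset containers and NPZ/PNG/JSON input-output.

A phantom dataset bundles rendered 3-channel strain images with their
binary infarct masks, per-sample infarct fractions (used for stratified
splitting) and a fidelity tag.  Datasets serialize to an NPZ bundle plus
a JSON manifest recording the generator seed, bounds and package version.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

from . import __version__
from .bullseye import BullseyeLayout, DEFAULT_WINDOWS, render_strain_image
from .phantoms import (FidelityShift, PhantomSpec, apply_fidelity_shift,
                       generate_strain_field)

#: Seed offset separating the fidelity-shift noise stream from the
#: phantom's own noise stream.
_SHIFT_SEED_OFFSET = 7_919


@dataclass
class PhantomDataset:
    """Images (N, H, W, 3 in [0,1]), masks (N, H, W in {0,1}), metadata."""

    images: np.ndarray
    masks: np.ndarray
    fractions: np.ndarray | None = None
    fidelity: str = "low"
    subject_ids: np.ndarray | None = None

    def __post_init__(self):
        self.images = np.asarray(self.images, dtype=np.float32)
        self.masks = np.asarray(self.masks, dtype=np.uint8)
        if self.images.ndim != 4 or self.images.shape[-1] != 3:
            raise ValueError("images must be (N, H, W, 3)")
        if self.masks.shape != self.images.shape[:3]:
            raise ValueError("masks must be (N, H, W) matching images")
        if self.subject_ids is None:
            self.subject_ids = np.arange(len(self.images))

    def __len__(self):
        return len(self.images)

    @property
    def resolution(self) -> int:
        return self.images.shape[1]

    def subset(self, idx) -> "PhantomDataset":
        idx = np.asarray(idx)
        return PhantomDataset(
            images=self.images[idx], masks=self.masks[idx],
            fractions=None if self.fractions is None else self.fractions[idx],
            fidelity=self.fidelity, subject_ids=self.subject_ids[idx])

    def pairs(self):
        """(image, mask) tuples, the augmentation interface."""
        return list(zip(self.images, self.masks))

    # -- serialization -----------------------------------------------------
    def save(self, path, manifest: dict | None = None):
        path = Path(path)
        arrays = {"images": self.images, "masks": self.masks,
                  "subject_ids": self.subject_ids}
        if self.fractions is not None:
            arrays["fractions"] = self.fractions
        np.savez(path.with_suffix(".npz"), **arrays)
        meta = {"fidelity": self.fidelity, "n": len(self),
                "resolution": self.resolution, "version": __version__}
        meta.update(manifest or {})
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, path) -> "PhantomDataset":
        path = Path(path)
        with np.load(path.with_suffix(".npz")) as data:
            fractions = data["fractions"] if "fractions" in data else None
            meta_path = path.with_suffix(".json")
            fidelity = "low"
            if meta_path.exists():
                fidelity = json.loads(meta_path.read_text()).get("fidelity", "low")
            return cls(images=data["images"], masks=data["masks"],
                       fractions=fractions, fidelity=fidelity,
                       subject_ids=data["subject_ids"])

    def export_mask_pngs(self, directory):
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for i, mask in enumerate(self.masks):
            Image.fromarray((mask * 255).astype(np.uint8), mode="L").save(
                directory / f"mask_{i:04d}.png")


def build_dataset(specs, layout: BullseyeLayout | None = None,
                  shift: FidelityShift | None = None,
                  windows: dict | None = None) -> PhantomDataset:
    """Render a list of phantom specs into an image/mask dataset.

    When ``shift`` is given the strain fields are passed through the
    fidelity distortion before rendering (high-fidelity emulation); the
    shift noise stream is seeded per phantom, offset from the phantom's
    own noise seed.
    """
    layout = layout or BullseyeLayout()
    windows = windows or DEFAULT_WINDOWS
    images, masks, fractions = [], [], []
    fidelity = "low"
    for spec in specs:
        field, mask = generate_strain_field(spec, layout)
        if shift is not None:
            field = apply_fidelity_shift(field, shift,
                                         seed=spec.seed + _SHIFT_SEED_OFFSET)
            fidelity = "high"
        images.append(render_strain_image(field, layout, windows))
        masks.append(mask)
        fractions.append(spec.infarct_fraction)
        if spec.fidelity == "high":
            fidelity = "high"
    return PhantomDataset(images=np.stack(images).astype(np.float32),
                          masks=np.stack(masks),
                          fractions=np.asarray(fractions),
                          fidelity=fidelity)


# -- image/mask PNG round-trip ----------------------------------------------

def save_image_png(image: np.ndarray, path):
    """Lossless 8-bit PNG export of a [0,1] image (greyscale or 3-channel)."""
    arr = np.clip(np.asarray(image, dtype=np.float64), 0, 1)
    arr8 = np.round(arr * 255).astype(np.uint8)
    mode = "L" if arr8.ndim == 2 else "RGB"
    Image.fromarray(arr8, mode=mode).save(path)


def load_image_png(path) -> np.ndarray:
    """Load a PNG back to float [0,1]."""
    return np.asarray(Image.open(path), dtype=np.float64) / 255.0


def to_nchw(dataset_pairs):
    """Stack (image HWC, mask HW) pairs into NCHW inputs and N1HW targets."""
    images = np.stack([np.moveaxis(np.asarray(img, dtype=np.float32), -1, 0)
                       for img, _ in dataset_pairs])
    masks = np.stack([np.asarray(m, dtype=np.float32)[None]
                      for _, m in dataset_pairs])
    return images, masks
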