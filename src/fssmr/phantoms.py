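"""Synthetic kidney CT phantoms.

Generates small grayscale images that mimic abdominal-CT crops around a
kidney: a smooth noisy background, a brighter elliptical kidney region,
and a class-specific lesion blob (cyst / stone / tumor) with a matching
binary mask.  Phantoms make the whole segmentation+classification
pipeline testable at desk scale without any external imaging data.

Class appearance conventions:

* ``normal`` — kidney only, empty mask.
* ``cyst``   — round, darker-than-parenchyma blob (fluid-filled).
* ``stone``  — small, very bright blob (calcification).
* ``tumor``  — larger irregular blob (union of jittered discs), mildly
  hyperintense.

All randomness flows through explicitly seeded ``numpy.random.Generator``
instances; the same ``(spec, label, seed)`` always yields bit-identical
samples.
"""

from __future__ import annotations

import csv
import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage

CLASSES = ("normal", "cyst", "stone", "tumor")

__all__ = [
    "CLASSES",
    "PhantomSpec",
    "LabeledSample",
    "generate_phantom",
    "augment",
    "generate_dataset",
    "save_dataset",
    "load_dataset",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and intensity parameters of the phantom generator.

    Defaults target a 46x46 plane, the input size of the multi-stream
    network.  Radii are in pixels, intensities in the [0, 1] gray scale.
    """

    image_size: int = 46
    background_level: float = 0.25
    background_noise_sd: float = 0.05
    kidney_axes: tuple[float, float] = (16.0, 11.0)
    kidney_level: float = 0.30
    lesion_params_per_class: dict = field(
        default_factory=lambda: {
            "cyst": {"radius": (4.0, 6.5), "offset": -0.35},
            "stone": {"radius": (1.5, 3.0), "offset": 0.55},
            "tumor": {"radius": (3.0, 5.5), "offset": 0.30},
        }
    )
    normalize: bool = True

    def __post_init__(self) -> None:
        # normalize sequence fields so configs loaded from YAML compare equal
        object.__setattr__(self, "kidney_axes", tuple(self.kidney_axes))
        object.__setattr__(
            self,
            "lesion_params_per_class",
            {
                cls: {"radius": tuple(p["radius"]), "offset": p["offset"]}
                for cls, p in self.lesion_params_per_class.items()
            },
        )
        if self.image_size < 8:
            raise ValueError(f"image_size must be >= 8, got {self.image_size}")
        half = self.image_size / 2
        for ax in self.kidney_axes:
            if ax >= half:
                raise ValueError(
                    f"kidney axis {ax} must be < image_size/2 = {half}"
                )
        for cls, p in self.lesion_params_per_class.items():
            if max(p["radius"]) >= half:
                raise ValueError(
                    f"{cls} lesion radius {p['radius']} must stay < {half}"
                )


@dataclass
class LabeledSample:
    """One grayscale image, its binary lesion mask, and a class label."""

    image: np.ndarray  # (H, W) float in [0, 1]
    mask: np.ndarray  # (H, W) uint8 in {0, 1}
    label: str

    def __post_init__(self) -> None:
        if self.image.shape != self.mask.shape:
            raise ValueError(
                f"image shape {self.image.shape} != mask shape {self.mask.shape}"
            )
        if self.label not in CLASSES:
            raise ValueError(
                f"unknown label {self.label!r}; valid labels are {CLASSES}"
            )


def _minmax(img: np.ndarray) -> np.ndarray:
    lo, hi = float(img.min()), float(img.max())
    if hi - lo < 1e-12:
        return np.zeros_like(img)
    return (img - lo) / (hi - lo)


def _disc(size: int, center: tuple[float, float], radius: float) -> np.ndarray:
    rr, cc = np.mgrid[0:size, 0:size]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def generate_phantom(spec: PhantomSpec, label: str, seed: int) -> LabeledSample:
    """Draw one phantom. Deterministic for fixed ``(spec, label, seed)``."""
    if label not in CLASSES:
        raise ValueError(
            f"unknown label {label!r}; valid labels are {CLASSES}"
        )
    if seed < 0:
        raise ValueError("seed must be a non-negative integer")
    rng = np.random.default_rng(seed)
    n = spec.image_size
    c = (n - 1) / 2.0

    # smooth noisy background
    img = spec.background_level + spec.background_noise_sd * rng.standard_normal((n, n))
    img = ndimage.gaussian_filter(img, sigma=1.0)

    # elliptical kidney, slightly rotated, brighter than background
    rr, cc = np.mgrid[0:n, 0:n]
    angle = rng.uniform(-0.4, 0.4)
    dr, dc = rr - c, cc - c
    u = dr * np.cos(angle) + dc * np.sin(angle)
    v = -dr * np.sin(angle) + dc * np.cos(angle)
    a, b = spec.kidney_axes
    kidney = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    img = img + spec.kidney_level * kidney
    img = img + 0.03 * ndimage.gaussian_filter(rng.standard_normal((n, n)), sigma=2.0)

    mask = np.zeros((n, n), dtype=np.uint8)
    if label != "normal":
        p = spec.lesion_params_per_class[label]
        r_lo, r_hi = p["radius"]
        radius = rng.uniform(r_lo, r_hi)
        # lesion center well inside the kidney ellipse
        t = rng.uniform(0, 2 * np.pi)
        rho = rng.uniform(0, 0.55)
        center = (c + rho * b * np.sin(t), c + rho * a * np.cos(t))
        if label == "tumor":
            blob = np.zeros((n, n), dtype=bool)
            for _ in range(int(rng.integers(2, 5))):
                jitter = rng.uniform(-radius / 2, radius / 2, size=2)
                sub_r = radius * rng.uniform(0.6, 1.0)
                blob |= _disc(n, (center[0] + jitter[0], center[1] + jitter[1]), sub_r)
        else:
            blob = _disc(n, center, radius)
        img = np.where(blob, img + p["offset"], img)
        mask[blob] = 1

    if spec.normalize:
        img = _minmax(img)
    else:
        img = np.clip(img, 0.0, 1.0)
    return LabeledSample(image=img, mask=mask, label=label)


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------

def _transform_pair(sample, img_fn, mask_fn):
    img = np.clip(img_fn(sample.image), 0.0, 1.0)
    mask = (mask_fn(sample.mask.astype(np.float64)) > 0.5).astype(np.uint8)
    return LabeledSample(image=img, mask=mask, label=sample.label)


def augment(sample: LabeledSample, op: str, seed: int = 0, **kw) -> LabeledSample:
    """Apply one geometric augmentation to image and mask identically.

    ``op`` is one of ``rotate`` (``angle`` in degrees, counter-clockwise),
    ``scale`` (``factor`` > 0, about the image center), ``flip``
    (``axis`` in {"horizontal", "vertical"}) and ``translate``
    (``dr``, ``dc`` in pixels, (row, col) convention, origin top-left).
    Images are interpolated bilinearly, masks nearest-neighbor so they
    stay binary; the label never changes.
    """
    if op == "rotate":
        angle = kw["angle"]
        return _transform_pair(
            sample,
            lambda a: ndimage.rotate(a, angle, reshape=False, order=1, mode="nearest"),
            lambda m: ndimage.rotate(m, angle, reshape=False, order=0, mode="constant"),
        )
    if op == "scale":
        factor = kw["factor"]
        if factor <= 0:
            raise ValueError(f"scale factor must be > 0, got {factor}")
        return _transform_pair(
            sample,
            lambda a: _zoom_about_center(a, factor, order=1),
            lambda m: _zoom_about_center(m, factor, order=0),
        )
    if op == "flip":
        axis = kw["axis"]
        if axis not in ("horizontal", "vertical"):
            raise ValueError("flip axis must be 'horizontal' or 'vertical'")
        ax = 1 if axis == "horizontal" else 0
        return _transform_pair(
            sample, lambda a: np.flip(a, axis=ax), lambda m: np.flip(m, axis=ax)
        )
    if op == "translate":
        dr, dc = kw["dr"], kw["dc"]
        return _transform_pair(
            sample,
            lambda a: ndimage.shift(a, (dr, dc), order=1, mode="constant", cval=0.0),
            lambda m: ndimage.shift(m, (dr, dc), order=0, mode="constant", cval=0.0),
        )
    raise ValueError(
        f"unknown augmentation {op!r}; expected rotate|scale|flip|translate"
    )


def _zoom_about_center(a: np.ndarray, factor: float, order: int) -> np.ndarray:
    """Zoom keeping the array shape, anchored at the geometric center."""
    n = a.shape[0]
    c = (n - 1) / 2.0
    rr, cc = np.mgrid[0:n, 0:n].astype(np.float64)
    coords = np.stack([(rr - c) / factor + c, (cc - c) / factor + c])
    return ndimage.map_coordinates(a, coords, order=order, mode="constant", cval=0.0)


# ---------------------------------------------------------------------------
# dataset generation and I/O
# ---------------------------------------------------------------------------

def class_counts(n: int, class_mix: dict[str, float]) -> dict[str, int]:
    """Largest-remainder apportionment of ``n`` samples over the classes.

    Ties in the remainder are broken in canonical class order
    (normal, cyst, stone, tumor).
    """
    for cls, p in class_mix.items():
        if p < 0:
            raise ValueError(f"negative proportion {p} for class {cls!r}")
    total_p = sum(class_mix.values())
    if abs(total_p - 1.0) > 1e-9:
        raise ValueError(f"class proportions must sum to 1, got {total_p}")
    quotas = {c: n * class_mix.get(c, 0.0) for c in CLASSES}
    counts = {c: int(np.floor(q)) for c, q in quotas.items()}
    remainder = n - sum(counts.values())
    by_frac = sorted(
        CLASSES, key=lambda c: (-(quotas[c] - counts[c]), CLASSES.index(c))
    )
    for c in by_frac[:remainder]:
        counts[c] += 1
    return counts


def generate_dataset(
    n: int,
    class_mix: dict[str, float] | None = None,
    spec: PhantomSpec | None = None,
    seed: int = 0,
) -> tuple[list[LabeledSample], dict]:
    """Generate ``n`` phantoms with per-class proportions ``class_mix``.

    Returns the samples plus a manifest dict recording the seed, spec and
    per-class counts.  Bit-reproducible for fixed arguments.
    """
    if n < 4:
        raise ValueError(f"need n >= 4 samples, got {n}")
    if class_mix is None:
        class_mix = {c: 0.25 for c in CLASSES}
    if spec is None:
        spec = PhantomSpec()
    counts = class_counts(n, class_mix)
    root_rng = np.random.default_rng(seed)
    samples: list[LabeledSample] = []
    records = []
    for cls in CLASSES:
        for i in range(counts[cls]):
            sub_seed = int(root_rng.integers(0, 2**31 - 1))
            samples.append(generate_phantom(spec, cls, sub_seed))
            records.append({"label": cls, "seed": sub_seed})
    manifest = {
        "n": n,
        "seed": seed,
        "spec": asdict(spec),
        "class_counts": counts,
        "records": records,
    }
    return samples, manifest


def save_dataset(samples: list[LabeledSample], manifest: dict, out_dir: str | Path) -> Path:
    """Write a dataset in the class-folder layout ``<root>/<class>/<name>.png``.

    Images are 8-bit grayscale PNGs, masks PNGs with values {0, 255}
    (suffix ``_mask``), plus ``manifest.csv`` (filename, label, seed) and
    ``manifest.json``.
    """
    out = Path(out_dir)
    rows = []
    for i, (s, rec) in enumerate(zip(samples, manifest["records"])):
        cls_dir = out / s.label
        cls_dir.mkdir(parents=True, exist_ok=True)
        name = f"{s.label}_{i:05d}"
        Image.fromarray((s.image * 255).round().astype(np.uint8)).save(
            cls_dir / f"{name}.png"
        )
        Image.fromarray((s.mask * 255).astype(np.uint8)).save(
            cls_dir / f"{name}_mask.png"
        )
        rows.append({"filename": f"{s.label}/{name}.png", "label": s.label,
                     "seed": rec["seed"]})
    with open(out / "manifest.csv", "w", newline="") as fh:
        w = csv.DictWriter(fh, fieldnames=["filename", "label", "seed"])
        w.writeheader()
        w.writerows(rows)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return out


def load_dataset(root: str | Path) -> list[LabeledSample]:
    """Load a dataset written by :func:`save_dataset`."""
    root = Path(root)
    samples = []
    with open(root / "manifest.csv") as fh:
        for row in csv.DictReader(fh):
            img_path = root / row["filename"]
            mask_path = img_path.with_name(img_path.stem + "_mask.png")
            img = np.asarray(Image.open(img_path), dtype=np.float64) / 255.0
            mask = (np.asarray(Image.open(mask_path)) > 127).astype(np.uint8)
            samples.append(LabeledSample(image=img, mask=mask, label=row["label"]))
    return samples


def manifest_checksum(root: str | Path) -> str:
    """SHA-256 over the sorted list of files and the manifest contents."""
    root = Path(root)
    h = hashlib.sha256()
    for p in sorted(root.rglob("*")):
        if p.is_file():
            h.update(str(p.relative_to(root)).encode())
            h.update(p.read_bytes())
    return h.hexdigest()
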