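"""Synthetic OCT-style vessel phantoms with per-class plaque masks.

Real intravascular OCT of coronary plaques is not publicly shareable, so
this module draws ring-shaped vessel cross-sections whose wall carries
angular plaque sectors of three texture classes, mimicking how the classes
read in clinical OCT:

* **calcified** — darker than the wall, sharply bounded (low reflectivity,
  clear boundary contours);
* **fibrous**   — brighter than the wall, homogeneous;
* **lipid**     — bright with a diffusely blurred border and a radial
  intensity fall-off toward the adventitia (the attenuation shadow).

Ground-truth masks mark the exact angular-sector support *before* any
blurring, so lipid masks delimit the true lesion, not its blurred halo.
The augmentation plan (rotation, flipping, additive Gaussian noise) is the
one used to expand the training set; geometric transforms are applied to
image and masks in lockstep, noise to the image only.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from PIL import Image
from scipy.ndimage import gaussian_filter
from skimage.transform import rotate as _sk_rotate

__all__ = ["PLAQUE_CLASSES", "PhantomSpec", "PhantomGeometry", "OctSample",
           "DatasetManifest", "draw_geometry", "render_phantom",
           "generate_phantom", "augment", "build_dataset", "load_sample",
           "load_manifest"]

PLAQUE_CLASSES = ("calcified", "fibrous", "lipid")

# noise-free intensity levels; chosen so calcified < wall < fibrous/lipid
_BACKGROUND = 0.05
_LUMEN = 0.08
_WALL = 0.50
_LEVEL = {"calcified": 0.18, "fibrous": 0.85, "lipid": 0.80}
_LIPID_BLUR_FRAC = 0.02        # boundary blur sigma, fraction of image size
_LIPID_ATTENUATION = 2.5       # e-folding rate of the radial fall-off


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and appearance parameters of one phantom family.

    Radii and thicknesses are fractions of the image half-width; sector
    angles are degrees.  ``sectors_per_class`` gives the inclusive range of
    how many sectors each requested class receives.
    """

    image_size: int = 128
    lumen_radius_range: tuple[float, float] = (0.25, 0.40)
    wall_thickness_range: tuple[float, float] = (0.25, 0.40)
    plaque_classes: tuple[str, ...] = PLAQUE_CLASSES
    sectors_per_class: tuple[int, int] = (1, 2)
    sector_angle_range: tuple[float, float] = (30.0, 70.0)
    noise_sigma: float = 0.02

    def __post_init__(self):
        if self.image_size < 16:
            raise ValueError("image_size too small")
        for cls in self.plaque_classes:
            if cls not in PLAQUE_CLASSES:
                raise ValueError(f"unknown plaque class {cls!r}")
        lo, hi = self.sector_angle_range
        if not (0.0 < lo <= hi <= 180.0):
            raise ValueError("sector angles must lie in (0, 180] degrees")
        if self.sectors_per_class[0] < 0:
            raise ValueError("sector counts must be >= 0")
        if self.lumen_radius_range[1] + self.wall_thickness_range[1] >= 1.0:
            raise ValueError("vessel may not fit: lumen radius + wall "
                             "thickness must stay below the half-width")


@dataclass
class OctSample:
    """One image (H, W, 3 in [0, 1]) with a binary mask per plaque class."""

    image: np.ndarray
    masks: dict[str, np.ndarray]
    case_id: str
    augmentation_tag: str = "original"

    def validate(self) -> None:
        h, w = self.image.shape[:2]
        if self.image.ndim != 3 or self.image.shape[2] != 3:
            raise ValueError("image must be H x W x 3")
        for cls, m in self.masks.items():
            if m.shape != (h, w):
                raise ValueError(f"mask {cls!r} shape mismatch")
            if not np.isin(m, (0, 1)).all():
                raise ValueError(f"mask {cls!r} is not binary")


@dataclass
class DatasetManifest:
    """Index of a written dataset: one entry per PNG image on disk.

    ``group`` is the case_id of the un-augmented parent, shared by all
    augmented copies — the unit at which cross-validation folds are cut.
    """

    root: Path
    entries: list[dict] = field(default_factory=list)

    @property
    def groups(self) -> list[str]:
        return sorted({e["group"] for e in self.entries})

    def class_counts(self) -> dict[str, int]:
        counts = dict.fromkeys(PLAQUE_CLASSES, 0)
        for e in self.entries:
            for cls in PLAQUE_CLASSES:
                counts[cls] += int(e[f"has_{cls}"])
        return counts

    def save(self, path: Path | None = None) -> Path:
        path = Path(path) if path else Path(self.root) / "manifest.json"
        payload = {"root": str(self.root), "entries": self.entries}
        path.write_text(json.dumps(payload, indent=1))
        # companion CSV for spreadsheet users
        csv_path = path.with_suffix(".csv")
        cols = ["case_id", "image", "mask_calcified", "mask_fibrous",
                "mask_lipid", "group"]
        with open(csv_path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=cols, extrasaction="ignore")
            writer.writeheader()
            writer.writerows(self.entries)
        return path


def load_manifest(path) -> DatasetManifest:
    payload = json.loads(Path(path).read_text())
    return DatasetManifest(root=Path(payload["root"]), entries=payload["entries"])


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _polar_grids(size: int) -> tuple[np.ndarray, np.ndarray]:
    """Radius (fraction of half-width) and angle (degrees in [0, 360))."""
    c = (size - 1) / 2.0
    y, x = np.mgrid[0:size, 0:size]
    r = np.hypot(x - c, y - c) / (size / 2.0)
    theta = np.degrees(np.arctan2(y - c, x - c)) % 360.0
    return r, theta


_SECTOR_GAP = 2.0  # degrees of clearance kept between adjacent sectors


def _place_sectors(widths: list[float], rng: np.random.Generator
                   ) -> list[tuple[float, float]]:
    """Choose non-overlapping (start, width) angular intervals, in degrees.

    Constructive: sectors are laid around the circle in a shuffled order,
    with the leftover arc split randomly (Dirichlet) into the gaps, so any
    feasible request succeeds.  A small fixed gap keeps distinct classes
    from sharing pixels after rasterisation.
    """
    n = len(widths)
    slack = 360.0 - sum(widths) - _SECTOR_GAP * n
    if slack < 0.0:
        raise ValueError(
            f"cannot place sectors totalling {sum(widths):.0f} degrees")
    order = rng.permutation(n)
    extras = rng.dirichlet(np.ones(n)) * slack
    pos = float(rng.uniform(0.0, 360.0))
    placed: list[tuple[float, float] | None] = [None] * n
    for i, idx in enumerate(order):
        placed[idx] = (pos % 360.0, widths[idx])
        pos += widths[idx] + _SECTOR_GAP + extras[i]
    return placed  # type: ignore[return-value]


def _sector_mask(r: np.ndarray, theta: np.ndarray, r0: float, r1: float,
                 start: float, width: float) -> np.ndarray:
    in_ring = (r >= r0) & (r < r1)
    rel = (theta - start) % 360.0
    return in_ring & (rel < width)


@dataclass(frozen=True)
class PhantomGeometry:
    """A fully specified phantom: ring radii plus placed plaque sectors.

    ``sectors`` holds (plaque_class, start_angle, width) triples in
    degrees.  Separated from the random draw so rendering is a pure
    function of the geometry.
    """

    lumen_radius: float
    wall_thickness: float
    sectors: tuple[tuple[str, float, float], ...] = ()


def draw_geometry(spec: PhantomSpec, rng: np.random.Generator) -> PhantomGeometry:
    """Sample one phantom geometry from the spec's parameter ranges."""
    lumen_r = float(rng.uniform(*spec.lumen_radius_range))
    thickness = float(rng.uniform(*spec.wall_thickness_range))
    if lumen_r + thickness >= 1.0:
        raise ValueError("vessel does not fit in the frame")
    # draw sector widths for every class; redraw if a draw asks for more
    # total arc than the circle can hold
    plan: list[tuple[str, float]] = []
    for _ in range(50):
        plan = []
        for cls in PLAQUE_CLASSES:                  # fixed order: determinism
            if cls not in spec.plaque_classes:
                continue
            n = int(rng.integers(spec.sectors_per_class[0],
                                 spec.sectors_per_class[1] + 1))
            for _ in range(n):
                plan.append((cls,
                             float(rng.uniform(*spec.sector_angle_range))))
        if sum(w for _, w in plan) + _SECTOR_GAP * len(plan) <= 360.0:
            break
    if plan and thickness * spec.image_size / 2.0 < 2.0:
        raise ValueError("wall too thin to carry plaque sectors")
    placed = _place_sectors([w for _, w in plan], rng) if plan else []
    return PhantomGeometry(
        lumen_radius=lumen_r, wall_thickness=thickness,
        sectors=tuple((cls, start, width)
                      for (cls, _), (start, width) in zip(plan, placed)))


def render_phantom(geometry: PhantomGeometry, spec: PhantomSpec,
                   rng: np.random.Generator) -> OctSample:
    """Rasterise a geometry into an image and its per-class masks.

    Masks are the discretised angular-sector support (per-pixel polar
    test) before lipid blurring; ``rng`` is used only for the additive
    noise and the case identifier.
    """
    size = spec.image_size
    lumen_r = geometry.lumen_radius
    thickness = geometry.wall_thickness
    r, theta = _polar_grids(size)
    wall = (r >= lumen_r) & (r < lumen_r + thickness)

    gray = np.full((size, size), _BACKGROUND, np.float32)
    gray[r < lumen_r] = _LUMEN
    gray[wall] = _WALL

    masks = {cls: np.zeros((size, size), np.uint8) for cls in PLAQUE_CLASSES}
    for cls, start, width in geometry.sectors:
        sector = _sector_mask(r, theta, lumen_r, lumen_r + thickness,
                              start, width)
        masks[cls] |= sector.astype(np.uint8)

    for cls in PLAQUE_CLASSES:
        m = masks[cls].astype(bool)
        if not m.any():
            continue
        if cls == "lipid":
            # bright core with attenuating radial fall-off, then a diffuse
            # boundary: blur the lesion's contribution only
            depth = np.clip((r - lumen_r) / max(thickness, 1e-6), 0.0, 1.0)
            lesion = np.where(m, _LEVEL[cls] * np.exp(-_LIPID_ATTENUATION *
                                                      depth * 0.5), 0.0)
            delta = np.where(m, lesion - gray, 0.0)
            gray += gaussian_filter(delta, sigma=_LIPID_BLUR_FRAC * size)
        else:
            gray[m] = _LEVEL[cls]

    if spec.noise_sigma > 0:
        gray = gray + rng.normal(0.0, spec.noise_sigma,
                                 gray.shape).astype(np.float32)
    gray = np.clip(gray, 0.0, 1.0).astype(np.float32)
    image = np.repeat(gray[:, :, None], 3, axis=2)
    case_id = f"case_{rng.integers(0, 2 ** 31):08x}"
    sample = OctSample(image=image, masks=masks, case_id=case_id)
    sample.validate()
    return sample


def generate_phantom(spec: PhantomSpec, rng: np.random.Generator) -> OctSample:
    """Draw one ring-vessel phantom with its per-class ground-truth masks.

    Deterministic given the state of ``rng``; equivalent to rendering
    :func:`draw_geometry`'s output.
    """
    return render_phantom(draw_geometry(spec, rng), spec, rng)


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------

def augment(sample: OctSample, transform: str,
            rng: np.random.Generator | None = None, *,
            angle: float | None = None, axis: str = "horizontal",
            sigma: float = 0.02) -> OctSample:
    """Apply one augmentation; image and masks stay in lockstep.

    ``transform`` is one of ``rotate`` (bilinear for the image, nearest for
    masks, re-binarised at 0.5; exact right-angle rotations use lossless
    quarter-turns), ``flip`` (axis ``horizontal`` or ``vertical``) or
    ``add_noise`` (additive Gaussian on the image only, clipped to [0, 1]).
    """
    sample.validate()
    img, masks = sample.image, sample.masks
    if transform == "rotate":
        if angle is None:
            if rng is None:
                raise ValueError("rotate needs an angle or an rng")
            angle = float(rng.uniform(0.0, 360.0))
        if angle % 90.0 == 0.0:
            k = int(angle // 90) % 4
            new_img = np.rot90(img, k, axes=(0, 1)).copy()
            new_masks = {c: np.rot90(m, k).copy() for c, m in masks.items()}
        else:
            new_img = np.stack([_sk_rotate(img[:, :, c], angle, order=1,
                                           preserve_range=True)
                                for c in range(3)], axis=2).astype(np.float32)
            new_masks = {c: (_sk_rotate(m.astype(float), angle, order=0,
                                        preserve_range=True) >= 0.5
                             ).astype(np.uint8) for c, m in masks.items()}
        tag = f"rotate({angle:g})"
    elif transform == "flip":
        ax = {"horizontal": 1, "vertical": 0}.get(axis)
        if ax is None:
            raise ValueError(f"unknown flip axis {axis!r}")
        new_img = np.flip(img, axis=ax).copy()
        new_masks = {c: np.flip(m, axis=ax).copy() for c, m in masks.items()}
        tag = f"flip({axis})"
    elif transform == "add_noise":
        if rng is None:
            raise ValueError("add_noise needs an rng")
        new_img = np.clip(img + rng.normal(0.0, sigma, img.shape),
                          0.0, 1.0).astype(np.float32)
        new_masks = {c: m.copy() for c, m in masks.items()}
        tag = f"noise({sigma:g})"
    else:
        raise ValueError(f"unknown transform {transform!r}")
    prev = "" if sample.augmentation_tag == "original" else \
        sample.augmentation_tag + "+"
    return OctSample(image=new_img, masks=new_masks, case_id=sample.case_id,
                     augmentation_tag=prev + tag)


# ---------------------------------------------------------------------------
# dataset building and round-trip I/O
# ---------------------------------------------------------------------------

def _write_sample(sample: OctSample, out_dir: Path, stem: str) -> dict:
    img8 = np.round(sample.image * 255.0).astype(np.uint8)
    image_rel = f"images/{stem}.png"
    Image.fromarray(img8).save(out_dir / image_rel)
    entry = {"case_id": stem, "group": sample.case_id,
             "image": image_rel, "tag": sample.augmentation_tag}
    for cls in PLAQUE_CLASSES:
        rel = f"masks/{stem}_{cls}.png"
        Image.fromarray((sample.masks[cls] * 255).astype(np.uint8)).save(
            out_dir / rel)
        entry[f"mask_{cls}"] = rel
        entry[f"has_{cls}"] = bool(sample.masks[cls].any())
    return entry


def load_sample(manifest: DatasetManifest, entry: dict) -> OctSample:
    """Re-read one manifest entry from its PNGs."""
    root = Path(manifest.root)
    img = np.asarray(Image.open(root / entry["image"]),
                     np.float32) / 255.0
    masks = {cls: (np.asarray(Image.open(root / entry[f"mask_{cls}"])) > 127
                   ).astype(np.uint8) for cls in PLAQUE_CLASSES}
    return OctSample(image=img, masks=masks, case_id=entry["group"],
                     augmentation_tag=entry.get("tag", "original"))


def build_dataset(spec: PhantomSpec, n_originals: int, n_augmented: int,
                  out_dir, rng: np.random.Generator,
                  plaque_free_fraction: float = 80.0 / 760.0) -> DatasetManifest:
    """Write ``n_augmented`` PNG image/mask sets spanning ``n_originals`` cases.

    The first ``n_originals`` entries are the originals themselves; the rest
    are random rotation / flip / noise augmentations of randomly chosen
    originals.  ``plaque_free_fraction`` of the originals carry no plaque at
    all (the clinical mix is roughly 80 of 760).  Every entry's ``group``
    key is its parent's case_id, so grouped fold splits cannot leak
    augmented copies across folds.
    """
    if n_augmented < n_originals:
        raise ValueError("n_augmented must be >= n_originals")
    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    (out_dir / "masks").mkdir(parents=True, exist_ok=True)

    n_free = int(round(plaque_free_fraction * n_originals))
    originals: list[OctSample] = []
    for i in range(n_originals):
        s = spec if i >= n_free else replace(
            spec, plaque_classes=(), sectors_per_class=(0, 0))
        originals.append(generate_phantom(s, rng))

    manifest = DatasetManifest(root=out_dir)
    for i, sample in enumerate(originals):
        manifest.entries.append(_write_sample(sample, out_dir, f"img{i:05d}"))
    for i in range(n_originals, n_augmented):
        parent = originals[int(rng.integers(0, n_originals))]
        kind = ("rotate", "flip", "add_noise")[int(rng.integers(0, 3))]
        if kind == "flip":
            aug = augment(parent, "flip",
                          axis=("horizontal", "vertical")[int(rng.integers(0, 2))])
        else:
            aug = augment(parent, kind, rng, sigma=max(spec.noise_sigma, 0.01))
        manifest.entries.append(_write_sample(aug, out_dir, f"img{i:05d}"))
    manifest.save()
    return manifest
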