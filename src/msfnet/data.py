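"""Dataset handling: image-folder ingestion, augmentation, splits, synthesis.

The on-disk layout is one directory per class of PNG/JPEG images (the layout
of public leaf-disease collections such as the five-class cassava set: CBB,
CBSD, CGM, CMD, healthy).  A :class:`DatasetManifest` lists (image, label)
records against an ordered class vocabulary and is the unit every other
module consumes.

The augmentation recipe is fixed and offline: each source image contributes
itself plus a 180° rotation, a ×0.7 brightness reduction, and a horizontal
flip, each provenance-tagged.  Splitting is deterministic largest-remainder
apportionment (per class when stratified), and is meant to run *before*
augmentation so variants of one photograph never straddle train and test.

A synthetic generator renders cassava-like leaf images — green textured
background plus class-specific lesion motifs — so the full pipeline runs and
is tested without any download.
"""

from __future__ import annotations

import csv
import os
import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
from PIL import Image, ImageDraw, UnidentifiedImageError
from scipy import ndimage

from .errors import ConfigurationError, DataError, ValidationError

ImageRef = Union[str, np.ndarray]

IMAGE_EXTENSIONS = (".png", ".jpg", ".jpeg")


# ---------------------------------------------------------------------------
# manifest types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Record:
    """One dataset entry: an image (path or in-memory array) with its label.

    ``provenance`` is "original" or the name of the augmentation that
    produced the record; ``transform`` names a transform still to be applied
    at load time (for non-materialized variants).
    """

    image: ImageRef
    label: str
    identifier: str
    provenance: str = "original"
    transform: str = "none"


@dataclass(frozen=True)
class DatasetManifest:
    records: Tuple[Record, ...]
    classes: Tuple[str, ...]
    exclusions: Tuple[Tuple[str, str], ...] = ()  # (path, reason)

    def __post_init__(self):
        if len(self.records) < 1:
            raise DataError("manifest must contain at least one record")
        vocab = set(self.classes)
        for r in self.records:
            if r.label not in vocab:
                raise DataError(f"record label {r.label!r} not in class vocabulary")

    def __len__(self) -> int:
        return len(self.records)

    def labels(self) -> np.ndarray:
        index = {c: i for i, c in enumerate(self.classes)}
        return np.array([index[r.label] for r in self.records], dtype=int)

    def class_counts(self) -> Dict[str, int]:
        counts = {c: 0 for c in self.classes}
        for r in self.records:
            counts[r.label] += 1
        return counts


@dataclass(frozen=True)
class SplitSpec:
    """Train/val/test ratios (must sum to 1), RNG seed, stratification flag."""

    ratios: Tuple[float, float, float] = (0.8, 0.1, 0.1)
    seed: int = 0
    stratified: bool = True

    def __post_init__(self):
        if len(self.ratios) != 3 or any(r < 0 for r in self.ratios):
            raise ConfigurationError(f"ratios must be 3 nonnegative reals, got {self.ratios}")
        if abs(sum(self.ratios) - 1.0) > 1e-9:
            raise ConfigurationError(f"ratios must sum to 1, got sum={sum(self.ratios)}")


NINETY_TEN = SplitSpec(ratios=(0.9, 0.0, 0.1))  # the coarse train/test preset


# ---------------------------------------------------------------------------
# ingestion
# ---------------------------------------------------------------------------

def load_image_folder(root: str, verify: bool = True) -> DatasetManifest:
    """Scan a directory-per-class tree into a deterministic manifest.

    Class names come from subdirectory names (lexicographic order); files
    are listed lexicographically within each class.  Unreadable images are
    recorded in the manifest's exclusion report rather than silently
    dropped; an empty class directory produces a warning.
    """
    if not os.path.isdir(root):
        raise DataError(f"dataset root is not a directory: {root}")
    classes = sorted(
        d for d in os.listdir(root) if os.path.isdir(os.path.join(root, d))
    )
    if not classes:
        raise DataError(f"no class subdirectories under {root}")
    records: List[Record] = []
    exclusions: List[Tuple[str, str]] = []
    for cls in classes:
        cdir = os.path.join(root, cls)
        files = sorted(
            f for f in os.listdir(cdir) if f.lower().endswith(IMAGE_EXTENSIONS)
        )
        if not files:
            warnings.warn(f"class directory has no images: {cdir}", stacklevel=2)
        for f in files:
            path = os.path.join(cdir, f)
            if verify:
                try:
                    with Image.open(path) as im:
                        im.verify()
                except (OSError, UnidentifiedImageError, SyntaxError) as exc:
                    exclusions.append((path, str(exc)))
                    continue
            records.append(Record(image=path, label=cls, identifier=f"{cls}/{f}"))
    if not records:
        raise DataError(f"no readable images under {root}")
    return DatasetManifest(tuple(records), tuple(classes), tuple(exclusions))


def load_record_image(record: Record) -> np.ndarray:
    """Materialize a record as an uint8 H×W×3 RGB array (transform applied)."""
    if isinstance(record.image, np.ndarray):
        img = record.image.copy()
    else:
        try:
            with Image.open(record.image) as im:
                img = np.asarray(im.convert("RGB"))
        except (OSError, UnidentifiedImageError) as exc:
            raise DataError(f"unreadable image {record.image}: {exc}") from exc
    return apply_transform(img, record.transform)


# ---------------------------------------------------------------------------
# augmentations
# ---------------------------------------------------------------------------

def _check_image(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValidationError(f"expected H×W×3 image, got shape {img.shape}")
    return img


def rotate180(img: np.ndarray) -> np.ndarray:
    """Rotate by 180°: pixel (i, j) → (H-1-i, W-1-j). An involution."""
    return _check_image(img)[::-1, ::-1].copy()


def hflip(img: np.ndarray) -> np.ndarray:
    """Mirror left-right: column j → W-1-j. An involution."""
    return _check_image(img)[:, ::-1].copy()


def vflip(img: np.ndarray) -> np.ndarray:
    """Mirror top-bottom (rotate180 == hflip ∘ vflip)."""
    return _check_image(img)[::-1, :].copy()


def adjust_brightness(img: np.ndarray, factor: float) -> np.ndarray:
    """Scale all channels by ``factor`` (0.7 = the dimming used offline).

    Rounding is half-away-from-zero, then the result is clipped to [0, 255],
    so repeated application is bit-stable.
    """
    if factor <= 0:
        raise ValidationError(f"brightness factor must be > 0, got {factor}")
    img = _check_image(img).astype(np.float64)
    out = np.floor(img * factor + 0.5)  # values are nonnegative
    return np.clip(out, 0, 255).astype(np.uint8)


def apply_transform(img: np.ndarray, transform: str) -> np.ndarray:
    if transform in ("none", ""):
        return img
    if transform == "rotate180":
        return rotate180(img)
    if transform == "hflip":
        return hflip(img)
    if transform.startswith("brightness:"):
        return adjust_brightness(img, float(transform.split(":", 1)[1]))
    raise ConfigurationError(f"unknown transform: {transform!r}")


DEFAULT_RECIPE: Tuple[Tuple[str, str], ...] = (
    ("rotate180", "rotate180"),
    ("brightness0.7", "brightness:0.7"),
    ("hflip", "hflip"),
)
BRIGHTEN_VARIANT = ("brightness1.3", "brightness:1.3")  # optional, off by default


def augment_dataset(
    manifest: DatasetManifest,
    recipe: Sequence[Tuple[str, str]] = DEFAULT_RECIPE,
    per_class_cap: Optional[int] = None,
    out_dir: Optional[str] = None,
) -> DatasetManifest:
    """Emit originals plus the recipe's derived variants per image.

    Ordering per class is: all originals, then each variant kind in recipe
    order across all images — so a ``per_class_cap`` keeps whole variant
    waves before partially filling with the next (deterministic truncation).
    With ``out_dir`` set, variant images are written to disk (materialized);
    otherwise variant records carry a load-time transform tag.
    """
    by_class: Dict[str, List[Record]] = {c: [] for c in manifest.classes}
    for r in manifest.records:
        by_class[r.label].append(r)

    out_records: List[Record] = []
    for cls in manifest.classes:
        rows: List[Record] = list(by_class[cls])
        for variant_name, transform in recipe:
            for r in by_class[cls]:
                ident = f"{r.identifier}#{variant_name}"
                if out_dir is not None:
                    img = apply_transform(load_record_image(r), transform)
                    cdir = os.path.join(out_dir, cls)
                    os.makedirs(cdir, exist_ok=True)
                    fname = f"{os.path.basename(str(r.identifier)).replace('/', '_')}_{variant_name}.png"
                    fpath = os.path.join(cdir, fname)
                    Image.fromarray(img).save(fpath)
                    rows.append(Record(fpath, cls, ident, provenance=variant_name))
                else:
                    rows.append(
                        Record(r.image, cls, ident, provenance=variant_name, transform=transform)
                    )
        if per_class_cap is not None:
            rows = rows[:per_class_cap]
        out_records.extend(rows)
    return DatasetManifest(tuple(out_records), manifest.classes, manifest.exclusions)


# ---------------------------------------------------------------------------
# splitting
# ---------------------------------------------------------------------------

def _apportion(n: int, ratios: Sequence[float]) -> List[int]:
    """Largest-remainder apportionment of n items over ratios (sum to n)."""
    quotas = [n * r for r in ratios]
    counts = [int(np.floor(q)) for q in quotas]
    remainder = n - sum(counts)
    # distribute leftovers by largest fractional part; ties favour earlier splits
    order = sorted(range(len(ratios)), key=lambda i: (-(quotas[i] - counts[i]), i))
    for i in order[:remainder]:
        counts[i] += 1
    return counts


def split_dataset(
    manifest: DatasetManifest, spec: SplitSpec
) -> Tuple[Optional[DatasetManifest], Optional[DatasetManifest], Optional[DatasetManifest]]:
    """Partition into (train, val, test); disjoint, exhaustive, seeded.

    Counts follow largest-remainder apportionment of the ratios — per class
    when stratified, globally otherwise.  An empty split is returned as
    ``None``.
    """
    rng = np.random.default_rng(spec.seed)
    buckets: Tuple[List[Record], List[Record], List[Record]] = ([], [], [])

    def assign(records: List[Record]) -> None:
        idx = rng.permutation(len(records))
        counts = _apportion(len(records), spec.ratios)
        start = 0
        for b, c in enumerate(counts):
            for i in idx[start : start + c]:
                buckets[b].append(records[i])
            start += c

    if spec.stratified:
        for cls in manifest.classes:
            assign([r for r in manifest.records if r.label == cls])
    else:
        assign(list(manifest.records))

    def build(records: List[Record]) -> Optional[DatasetManifest]:
        if not records:
            return None
        return DatasetManifest(tuple(records), manifest.classes)

    return build(buckets[0]), build(buckets[1]), build(buckets[2])


# ---------------------------------------------------------------------------
# manifest CSV round-trip
# ---------------------------------------------------------------------------

def manifest_to_csv(manifest: DatasetManifest, path: str, split: str = "") -> None:
    """Write path,label,split,provenance rows (in-memory images unsupported)."""
    os.makedirs(os.path.dirname(os.path.abspath(path)) or ".", exist_ok=True)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["path", "label", "split", "provenance"])
        for r in manifest.records:
            if isinstance(r.image, np.ndarray):
                raise DataError("cannot export in-memory images to CSV; materialize first")
            writer.writerow([r.image, r.label, split, r.provenance])


def manifest_from_csv(path: str) -> DatasetManifest:
    records: List[Record] = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            records.append(
                Record(row["path"], row["label"], row["path"], provenance=row.get("provenance", "original"))
            )
    if not records:
        raise DataError(f"empty manifest CSV: {path}")
    classes = tuple(sorted({r.label for r in records}))
    return DatasetManifest(tuple(records), classes)


# ---------------------------------------------------------------------------
# synthetic cassava-like image generator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MotifSpec:
    """Rendering parameters for one class's lesion motif."""

    motif: str                      # blotch | streak | mottle | mosaic | none
    color: Tuple[int, int, int]
    count_range: Tuple[int, int] = (4, 8)
    size_range: Tuple[float, float] = (0.06, 0.16)  # fraction of min(H, W)


# Default five-class specification mirroring the cassava vocabulary:
# bacterial blight (pale angular blotches), brown streak (elongated brown
# streaks), green mottle (green-on-green dots), mosaic (yellow patches),
# and healthy leaves (no lesions).
DEFAULT_CLASS_SPECS: Dict[str, MotifSpec] = {
    "cbb": MotifSpec("blotch", (205, 198, 160), (4, 8), (0.08, 0.20)),
    "cbsd": MotifSpec("streak", (112, 72, 30), (5, 10), (0.15, 0.40)),
    "cgm": MotifSpec("mottle", (110, 170, 80), (25, 45), (0.02, 0.05)),
    "cmd": MotifSpec("mosaic", (210, 205, 70), (4, 9), (0.08, 0.18)),
    "healthy": MotifSpec("none", (0, 0, 0), (0, 0)),
}

BACKGROUND_GREEN = (52, 110, 46)
BACKGROUND_NOISE_SD = 6.0


def synthesize_image(
    class_name: str,
    rng: np.random.Generator,
    image_size: Tuple[int, int] = (600, 800),
    class_specs: Optional[Dict[str, MotifSpec]] = None,
    noise_sd: float = BACKGROUND_NOISE_SD,
) -> np.ndarray:
    """Render one uint8 H×W×3 leaf-like image for ``class_name``."""
    specs = class_specs or DEFAULT_CLASS_SPECS
    if class_name not in specs:
        raise ConfigurationError(f"no motif spec for class {class_name!r}")
    spec = specs[class_name]
    h, w = image_size

    # leaf-green background with smooth low-frequency shading
    base = np.empty((h, w, 3), dtype=np.float64)
    coarse = rng.normal(0.0, 12.0, (max(2, h // 16), max(2, w // 16)))
    shading = ndimage.zoom(coarse, (h / coarse.shape[0], w / coarse.shape[1]), order=1)
    shading = shading[:h, :w]
    for c, v in enumerate(BACKGROUND_GREEN):
        base[:, :, c] = v + shading

    img = Image.fromarray(np.clip(base, 0, 255).astype(np.uint8))
    draw = ImageDraw.Draw(img)
    scale = min(h, w)

    def jitter_color() -> Tuple[int, int, int]:
        return tuple(
            int(np.clip(v + rng.integers(-15, 16), 0, 255)) for v in spec.color
        )

    if spec.motif != "none":
        n = int(rng.integers(spec.count_range[0], spec.count_range[1] + 1))
        for _ in range(n):
            cx = float(rng.uniform(0, w))
            cy = float(rng.uniform(0, h))
            s = float(rng.uniform(*spec.size_range)) * scale
            color = jitter_color()
            if spec.motif == "blotch":
                pts = [
                    (
                        cx + s * np.cos(a) * rng.uniform(0.5, 1.0),
                        cy + s * np.sin(a) * rng.uniform(0.5, 1.0),
                    )
                    for a in np.linspace(0, 2 * np.pi, 6, endpoint=False)
                ]
                draw.polygon(pts, fill=color)
            elif spec.motif == "streak":
                angle = rng.uniform(0, np.pi)
                dx, dy = s * np.cos(angle), s * np.sin(angle)
                width = max(1, int(0.015 * scale))
                draw.line([(cx - dx, cy - dy), (cx + dx, cy + dy)], fill=color, width=width)
            elif spec.motif == "mottle":
                draw.ellipse([cx - s, cy - s, cx + s, cy + s], fill=color)
            elif spec.motif == "mosaic":
                ww, hh = s * rng.uniform(0.7, 1.3), s * rng.uniform(0.7, 1.3)
                draw.rectangle([cx - ww, cy - hh, cx + ww, cy + hh], fill=color)

    out = np.asarray(img).astype(np.float64)
    out += rng.normal(0.0, noise_sd, out.shape)
    return np.clip(out, 0, 255).astype(np.uint8)


def generate_synthetic_dataset(
    out_dir: str,
    n_per_class: Union[int, Dict[str, int]] = 50,
    image_size: Tuple[int, int] = (600, 800),
    class_specs: Optional[Dict[str, MotifSpec]] = None,
    seed: int = 0,
    noise_sd: float = BACKGROUND_NOISE_SD,
) -> DatasetManifest:
    """Materialize a directory-per-class synthetic image folder.

    Deterministic given ``seed`` (each image drawn from a child generator
    keyed by class and index, so per-class counts can change without
    perturbing other images).  ``n_per_class`` may be a dict for imbalance.
    """
    specs = class_specs or DEFAULT_CLASS_SPECS
    classes = tuple(sorted(specs))
    if isinstance(n_per_class, int):
        if n_per_class < 1:
            raise ConfigurationError("n_per_class must be >= 1")
        counts = {c: n_per_class for c in classes}
    else:
        counts = {c: int(n_per_class.get(c, 0)) for c in classes}
    records: List[Record] = []
    for ci, cls in enumerate(classes):
        cdir = os.path.join(out_dir, cls)
        os.makedirs(cdir, exist_ok=True)
        for i in range(counts[cls]):
            rng = np.random.default_rng([seed, ci, i])
            img = synthesize_image(cls, rng, image_size, specs, noise_sd)
            path = os.path.join(cdir, f"{cls}_{i:04d}.png")
            Image.fromarray(img).save(path)
            records.append(Record(path, cls, f"{cls}/{cls}_{i:04d}.png"))
    return DatasetManifest(tuple(records), classes)


def generate_synthetic_manifest(
    n_per_class: Union[int, Dict[str, int]] = 50,
    image_size: Tuple[int, int] = (64, 64),
    class_specs: Optional[Dict[str, MotifSpec]] = None,
    seed: int = 0,
    noise_sd: float = BACKGROUND_NOISE_SD,
) -> DatasetManifest:
    """In-memory variant of :func:`generate_synthetic_dataset` (no files)."""
    specs = class_specs or DEFAULT_CLASS_SPECS
    classes = tuple(sorted(specs))
    if isinstance(n_per_class, int):
        counts = {c: n_per_class for c in classes}
    else:
        counts = {c: int(n_per_class.get(c, 0)) for c in classes}
    records: List[Record] = []
    for ci, cls in enumerate(classes):
        for i in range(counts[cls]):
            rng = np.random.default_rng([seed, ci, i])
            img = synthesize_image(cls, rng, image_size, specs, noise_sd)
            records.append(Record(img, cls, f"{cls}/{i:04d}"))
    return DatasetManifest(tuple(records), classes)
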