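"""Dataset layout, label schema, mask serialization and augmentation.

The corpus follows the PASCAL-VOC-2012 segmentation conventions the
surgical dataset adopts: RGB frames under ``JPEGImages/``, palette-
indexed PNG class masks under ``SegmentationClass/``, split lists under
``ImageSets/Segmentation/`` and a ``manifest.json`` carrying per-sample
patient metadata (age group, gender) plus the per-channel normalization
statistics computed over the training split.

The ten-class schema: background plus four cranial nerves (cn5, cn7,
cn9, cn10), three vessels (aica, pica, pv) and the two composite
vessel-over-nerve classes (aica+cn7, pica+cn7) that mark the
compression interface.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml
from PIL import Image
from scipy import ndimage

from .errors import InvalidInputError, SchemaError

__all__ = [
    "LabelSchema",
    "SceneSample",
    "AugmentationConfig",
    "voc_palette",
    "write_mask",
    "read_mask",
    "split_manifest",
    "augment",
    "Corpus",
    "write_corpus",
    "load_corpus",
    "AGE_GROUPS",
    "GENDERS",
]

AGE_GROUPS = ("40-50", "50-60", "60-70")
GENDERS = ("male", "female")

#: (abbreviation, full name) in canonical index order; background is 0.
CLASS_TABLE = (
    ("background", "Background"),
    ("cn5", "Trigeminal nerve"),
    ("cn7", "Facial nerve"),
    ("cn9", "Glossopharyngeal nerve"),
    ("cn10", "Vagus nerve"),
    ("aica", "Anterior inferior cerebellar artery"),
    ("pica", "Posterior inferior cerebellar artery"),
    ("aica+cn7", "Anterior inferior cerebellar artery and facial nerve"),
    ("pica+cn7", "Posterior inferior cerebellar artery and facial nerve"),
    ("pv", "Petrosal vein"),
)


def voc_palette(n: int) -> np.ndarray:
    """First ``n`` colors of the standard PASCAL VOC label palette."""
    pal = np.zeros((n, 3), dtype=np.uint8)
    for i in range(n):
        c, j = i, 0
        r = g = b = 0
        while c:
            r |= ((c >> 0) & 1) << (7 - j)
            g |= ((c >> 1) & 1) << (7 - j)
            b |= ((c >> 2) & 1) << (7 - j)
            c >>= 3
            j += 1
        pal[i] = (r, g, b)
    return pal


@dataclass(frozen=True)
class LabelSchema:
    """Ordered class taxonomy with palette colors; index 0 is background."""

    entries: tuple = ()

    @classmethod
    def default(cls) -> "LabelSchema":
        pal = voc_palette(len(CLASS_TABLE))
        return cls(tuple(
            (i, abbr, full, tuple(int(v) for v in pal[i]))
            for i, (abbr, full) in enumerate(CLASS_TABLE)
        ))

    def __post_init__(self):
        colors = [e[3] for e in self.entries]
        if len(set(colors)) != len(colors):
            raise SchemaError("palette colors must be distinct")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def abbreviations(self) -> list[str]:
        return [e[1] for e in self.entries]

    @property
    def num_classes(self) -> int:
        return len(self.entries)

    def palette(self) -> np.ndarray:
        return np.array([e[3] for e in self.entries], dtype=np.uint8)

    def index_of(self, abbr: str) -> int:
        for i, a, _, _ in self.entries:
            if a == abbr:
                return i
        raise SchemaError(f"unknown class abbreviation {abbr!r}")

    def colorize(self, mask: np.ndarray) -> np.ndarray:
        """Map a label-index mask to an RGB visualization."""
        self.validate_mask(mask)
        return self.palette()[mask]

    def validate_mask(self, mask: np.ndarray) -> None:
        bad = np.setdiff1d(np.unique(mask), np.arange(len(self)))
        if bad.size:
            raise SchemaError(
                f"mask contains values outside the schema: {bad.tolist()}"
            )

    def to_yaml(self, path=None) -> str:
        d = {"classes": [
            {"index": i, "abbreviation": a, "name": f, "color": list(c)}
            for i, a, f, c in self.entries
        ]}
        text = yaml.safe_dump(d, sort_keys=False)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "LabelSchema":
        if isinstance(source, (str, Path)) and Path(source).exists():
            d = yaml.safe_load(Path(source).read_text())
        else:
            d = yaml.safe_load(source)
        return cls(tuple(
            (e["index"], e["abbreviation"], e["name"], tuple(e["color"]))
            for e in d["classes"]
        ))


@dataclass
class SceneSample:
    """One sample: RGB image, aligned label mask, split and metadata."""

    image: np.ndarray
    mask: np.ndarray
    split: str = "train"
    age_group: str = AGE_GROUPS[0]
    gender: str = GENDERS[0]
    seed: int = 0
    sample_id: str = ""

    def __post_init__(self):
        if self.image.shape[:2] != self.mask.shape:
            raise InvalidInputError(
                f"image {self.image.shape[:2]} and mask {self.mask.shape} "
                "spatial sizes differ"
            )


# ---------------------------------------------------------------------------
# mask serialization
# ---------------------------------------------------------------------------

def write_mask(mask: np.ndarray, schema: LabelSchema, path) -> None:
    """Write a label-index mask as a palette-indexed PNG."""
    schema.validate_mask(mask)
    img = Image.fromarray(mask.astype(np.uint8), mode="P")
    pal = np.zeros((256, 3), dtype=np.uint8)
    pal[: len(schema)] = schema.palette()
    img.putpalette(pal.reshape(-1).tolist())
    img.save(path)


def read_mask(path, schema: LabelSchema) -> np.ndarray:
    """Read a mask PNG; palette-indexed files map directly to indices,
    plain RGB files are decoded through the schema palette."""
    img = Image.open(path)
    if img.mode == "P":
        mask = np.asarray(img, dtype=np.int64)
    elif img.mode in ("RGB", "RGBA"):
        rgb = np.asarray(img.convert("RGB"), dtype=np.int64)
        pal = schema.palette().astype(np.int64)
        code = rgb[..., 0] * 65536 + rgb[..., 1] * 256 + rgb[..., 2]
        pal_code = pal[:, 0] * 65536 + pal[:, 1] * 256 + pal[:, 2]
        lut = {int(c): i for i, c in enumerate(pal_code)}
        mask = np.empty(code.shape, dtype=np.int64)
        uniq = np.unique(code)
        for u in uniq:
            if int(u) not in lut:
                r, g, b = u >> 16, (u >> 8) & 255, u & 255
                raise SchemaError(f"unknown palette color ({r}, {g}, {b}) in {path}")
        for u in uniq:
            mask[code == u] = lut[int(u)]
    else:
        raise SchemaError(f"unsupported mask image mode {img.mode!r}")
    schema.validate_mask(mask)
    return mask


# ---------------------------------------------------------------------------
# splits
# ---------------------------------------------------------------------------

def split_manifest(n_total: int, val_count: int, test_count: int,
                   seed: int) -> dict[str, list[int]]:
    """Randomly partition ``range(n_total)`` into train/val/test, with the
    train set as the complement of the two reserved sets."""
    if val_count < 0 or test_count < 0:
        raise InvalidInputError("split counts must be nonnegative")
    if val_count + test_count > n_total:
        raise InvalidInputError(
            f"val ({val_count}) + test ({test_count}) exceed total {n_total}"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(n_total)
    val = sorted(int(i) for i in order[:val_count])
    test = sorted(int(i) for i in order[val_count: val_count + test_count])
    train = sorted(int(i) for i in order[val_count + test_count:])
    return {"train": train, "val": val, "test": test}


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------

@dataclass
class AugmentationConfig:
    """Training-time augmentation: joint horizontal flip, image-only
    Gaussian blur and standardization, joint random crop."""

    flip_probability: float = 0.5
    blur_probability: float = 0.5
    blur_sigma: tuple[float, float] = (0.15, 1.15)
    mean: tuple[float, float, float] = (0.0, 0.0, 0.0)
    std: tuple[float, float, float] = (1.0, 1.0, 1.0)
    crop_size: int = 512

    def __post_init__(self):
        for p in (self.flip_probability, self.blur_probability):
            if not 0.0 <= p <= 1.0:
                raise InvalidInputError("probabilities must lie in [0, 1]")
        if any(s <= 0 for s in self.std):
            raise InvalidInputError("std must be strictly positive")
        if self.crop_size < 1:
            raise InvalidInputError("crop_size must be positive")


def standardize(image: np.ndarray, cfg: AugmentationConfig) -> np.ndarray:
    """Per-channel (x - mean) / std on a float copy of an H x W x 3 image."""
    img = np.asarray(image, dtype=np.float64)
    return (img - np.asarray(cfg.mean)) / np.asarray(cfg.std)


def _reflect_pad_to(image, mask, size):
    h, w = mask.shape
    ph, pw = max(0, size - h), max(0, size - w)
    if ph == 0 and pw == 0:
        return image, mask
    if ph >= h or pw >= w:
        raise InvalidInputError(
            f"crop {size} needs more reflect padding than the {h}x{w} input allows"
        )
    pad2 = ((0, ph), (0, pw))
    image = np.pad(image, pad2 + ((0, 0),), mode="reflect")
    mask = np.pad(mask, pad2, mode="reflect")
    return image, mask


def augment(sample: SceneSample, cfg: AugmentationConfig,
            rng: np.random.Generator) -> SceneSample:
    """Apply the training augmentations; geometry is shared between image
    and mask, photometric changes touch the image only.  The mask is
    never interpolated (flip and crop are exact index operations)."""
    image = np.asarray(sample.image, dtype=np.float64)
    mask = np.asarray(sample.mask)
    if rng.random() < cfg.flip_probability:
        image = image[:, ::-1].copy()
        mask = mask[:, ::-1].copy()
    if rng.random() < cfg.blur_probability:
        sigma = rng.uniform(*cfg.blur_sigma)
        image = ndimage.gaussian_filter(image, sigma=(sigma, sigma, 0))
    image = standardize(image, cfg)
    image, mask = _reflect_pad_to(image, mask, cfg.crop_size)
    h, w = mask.shape
    top = int(rng.integers(0, h - cfg.crop_size + 1))
    left = int(rng.integers(0, w - cfg.crop_size + 1))
    image = image[top: top + cfg.crop_size, left: left + cfg.crop_size]
    mask = mask[top: top + cfg.crop_size, left: left + cfg.crop_size]
    return replace(sample, image=image, mask=mask)


# ---------------------------------------------------------------------------
# corpus directory layout
# ---------------------------------------------------------------------------

@dataclass
class Corpus:
    """An on-disk VOC-style corpus plus its manifest."""

    root: Path
    schema: LabelSchema
    manifest: dict
    _cache: dict = field(default_factory=dict, repr=False)

    @property
    def normalization(self) -> tuple[np.ndarray, np.ndarray]:
        norm = self.manifest["normalization"]
        return np.asarray(norm["mean"]), np.asarray(norm["std"])

    def ids(self, split: str) -> list[str]:
        return [s["id"] for s in self.manifest["samples"] if s["split"] == split]

    def load(self, sample_id: str) -> SceneSample:
        if sample_id in self._cache:
            return self._cache[sample_id]
        meta = next(s for s in self.manifest["samples"] if s["id"] == sample_id)
        img = np.asarray(
            Image.open(self.root / "JPEGImages" / f"{sample_id}.png").convert("RGB")
        )
        mask = read_mask(self.root / "SegmentationClass" / f"{sample_id}.png", self.schema)
        sample = SceneSample(
            image=img, mask=mask, split=meta["split"],
            age_group=meta["age_group"], gender=meta["gender"],
            seed=meta["seed"], sample_id=sample_id,
        )
        self._cache[sample_id] = sample
        return sample

    def samples(self, split: str) -> list[SceneSample]:
        return [self.load(i) for i in self.ids(split)]


def write_corpus(samples: list[SceneSample], root, schema: LabelSchema | None = None,
                 extra_manifest: dict | None = None) -> Corpus:
    """Write samples to the VOC directory layout and build the manifest.

    Normalization statistics (per-channel mean/std over training images,
    on the 0-255 scale) are computed here and stored in the manifest.
    """
    root = Path(root)
    schema = schema or LabelSchema.default()
    (root / "JPEGImages").mkdir(parents=True, exist_ok=True)
    (root / "SegmentationClass").mkdir(parents=True, exist_ok=True)
    (root / "ImageSets" / "Segmentation").mkdir(parents=True, exist_ok=True)

    split_ids: dict[str, list[str]] = {"train": [], "val": [], "test": []}
    meta = []
    psum = np.zeros(3)
    psq = np.zeros(3)
    count = 0
    for s in samples:
        sid = s.sample_id or f"scene_{len(meta):05d}"
        Image.fromarray(s.image.astype(np.uint8)).save(root / "JPEGImages" / f"{sid}.png")
        write_mask(s.mask, schema, root / "SegmentationClass" / f"{sid}.png")
        split_ids.setdefault(s.split, []).append(sid)
        meta.append({"id": sid, "split": s.split, "age_group": s.age_group,
                     "gender": s.gender, "seed": int(s.seed)})
        if s.split == "train":
            img = s.image.reshape(-1, 3).astype(np.float64)
            psum += img.sum(axis=0)
            psq += (img ** 2).sum(axis=0)
            count += img.shape[0]
    if count == 0:
        mean = np.zeros(3)
        std = np.ones(3)
    else:
        mean = psum / count
        var = np.maximum(psq / count - mean ** 2, 1e-12)
        std = np.sqrt(var)

    for split, ids in split_ids.items():
        (root / "ImageSets" / "Segmentation" / f"{split}.txt").write_text(
            "".join(i + "\n" for i in ids)
        )
    schema.to_yaml(root / "classes.yaml")
    manifest = {
        "samples": meta,
        "normalization": {"mean": mean.tolist(), "std": std.tolist()},
    }
    if extra_manifest:
        manifest.update(extra_manifest)
    (root / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return Corpus(root=root, schema=schema, manifest=manifest)


def load_corpus(root) -> Corpus:
    root = Path(root)
    manifest_path = root / "manifest.json"
    if not manifest_path.exists():
        raise InvalidInputError(f"no manifest.json under {root}")
    manifest = json.loads(manifest_path.read_text())
    schema = LabelSchema.from_yaml(root / "classes.yaml")
    return Corpus(root=root, schema=schema, manifest=manifest)
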