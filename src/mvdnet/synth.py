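"""Synthetic surgical-scene generator.

Emulates the *label structure* of intraoperative microvascular
decompression imagery so the full train/eval pipeline runs without the
restricted hospital data: a low-frequency tissue background, band-like
cranial nerves and tubular vessels rasterized from random cubic
splines, composite vessel-over-nerve classes at forced crossings,
endoscopy-style specular highlights, sensor noise and mild blur.  No
claim of clinical realism is made - the point is thin elongated
structures with consistent per-class appearance and genuine composite
overlaps.

Determinism: every scene is a pure function of ``(config, seed)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage
from scipy.interpolate import CubicSpline

from .data import (
    AGE_GROUPS,
    GENDERS,
    Corpus,
    LabelSchema,
    SceneSample,
    split_manifest,
    write_corpus,
)
from .errors import InvalidSpecError

__all__ = ["SceneConfig", "generate_scene", "generate_corpus", "smoke_corpus"]

NERVE_CLASSES = ("cn5", "cn7", "cn9", "cn10")
VESSEL_CLASSES = ("aica", "pica", "pv")

#: rendering colors (RGB, 0-255); composites are blended at paint time
DEFAULT_COLORS = {
    "background": (172, 120, 112),
    "cn5": (225, 215, 140),
    "cn7": (248, 238, 180),
    "cn9": (205, 190, 115),
    "cn10": (235, 205, 95),
    "aica": (195, 55, 50),
    "pica": (150, 35, 60),
    "pv": (115, 45, 95),
}

#: per-scene appearance probability of each structural class
DEFAULT_CLASS_FREQUENCIES = {
    "cn5": 0.40, "cn7": 0.60, "cn9": 0.40, "cn10": 0.40,
    "aica": 0.50, "pica": 0.50, "pv": 0.45,
}

#: (vessel, nerve) -> composite class at their crossing
DEFAULT_OVERLAP_RULE = {("aica", "cn7"): "aica+cn7", ("pica", "cn7"): "pica+cn7"}

#: metadata proportions mirroring the stratified test-split group sizes
AGE_WEIGHTS = (107, 117, 84)
GENDER_WEIGHTS = (124, 184)


@dataclass
class SceneConfig:
    """Geometry and photometric priors of one synthetic scene."""

    width: int = 768
    height: int = 576
    class_frequencies: dict = field(default_factory=lambda: dict(DEFAULT_CLASS_FREQUENCIES))
    overlap_rule: dict = field(default_factory=lambda: dict(DEFAULT_OVERLAP_RULE))
    tube_width_frac: tuple[float, float] = (0.09, 0.17)
    curvature: float = 0.25
    highlight_strength: float = 25.0
    noise_sigma: float = 3.0
    blur_sigma: float = 0.5
    colors: dict = field(default_factory=lambda: dict(DEFAULT_COLORS))

    def __post_init__(self):
        if not any(p > 0 for p in self.class_frequencies.values()):
            raise InvalidSpecError("at least one class must have nonzero frequency")
        for name, p in self.class_frequencies.items():
            if not 0.0 <= p <= 1.0:
                raise InvalidSpecError(f"frequency of {name} outside [0, 1]")


def _smooth_field(rng, h, w, sigma_frac=0.12):
    """Zero-mean unit-ish low-frequency noise field."""
    f = ndimage.gaussian_filter(rng.normal(size=(h, w)), sigma=sigma_frac * min(h, w))
    s = f.std()
    return f / s if s > 0 else f


def _spline_points(rng, h, w, curvature, waypoint=None, n_samples=500):
    """Sample a smooth open curve crossing the canvas; optionally forced
    through ``waypoint`` (row, col)."""
    sides = rng.permutation(4)[:2]

    def border_point(side):
        t = rng.uniform(0.1, 0.9)
        return {
            0: (0.0, t * w), 1: (h - 1.0, t * w),
            2: (t * h, 0.0), 3: (t * h, w - 1.0),
        }[int(side)]

    p0 = border_point(sides[0])
    p3 = border_point(sides[1])
    jitter = curvature * min(h, w)
    mids = []
    for frac in (1 / 3, 2 / 3):
        base = (p0[0] + (p3[0] - p0[0]) * frac, p0[1] + (p3[1] - p0[1]) * frac)
        mids.append((base[0] + rng.normal(0, jitter), base[1] + rng.normal(0, jitter)))
    ctrl = [p0, mids[0], mids[1], p3]
    if waypoint is not None:
        ctrl[1 + int(rng.integers(0, 2))] = waypoint
    ctrl = np.array(ctrl)
    t = np.linspace(0, 1, len(ctrl))
    cs_r = CubicSpline(t, ctrl[:, 0])
    cs_c = CubicSpline(t, ctrl[:, 1])
    ts = np.linspace(0, 1, n_samples)
    return np.column_stack([cs_r(ts), cs_c(ts)])


def _footprint(points, h, w, width_px):
    """Boolean tube footprint: pixels within width/2 of the centerline."""
    grid = np.ones((h, w), dtype=bool)
    rr = np.round(points[:, 0]).astype(int)
    cc = np.round(points[:, 1]).astype(int)
    keep = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
    grid[rr[keep], cc[keep]] = False
    dist = ndimage.distance_transform_edt(grid)
    return dist <= width_px / 2.0


def generate_scene(cfg: SceneConfig, seed: int, schema: LabelSchema | None = None,
                   return_geometry: bool = False):
    """Render one scene deterministically from ``(cfg, seed)``.

    Returns a :class:`SceneSample` (uint8 image, uint8 mask, sampled
    metadata); with ``return_geometry=True`` also the per-class footprint
    dict used before rasterization noise, for consistency checks.
    """
    rng = np.random.default_rng(seed)
    schema = schema or LabelSchema.default()
    h, w = cfg.height, cfg.width

    # which structural classes appear
    names = [n for n in NERVE_CLASSES + VESSEL_CLASSES
             if cfg.class_frequencies.get(n, 0.0) > 0]
    present = [n for n in names if rng.random() < cfg.class_frequencies[n]]
    if not present:
        present = [names[int(rng.integers(0, len(names)))]]

    # geometry: nerves first (they sit under the vessels)
    centerlines: dict[str, np.ndarray] = {}
    footprints: dict[str, np.ndarray] = {}
    min_dim = min(h, w)
    for name in NERVE_CLASSES + VESSEL_CLASSES:
        if name not in present:
            continue
        waypoint = None
        if name in VESSEL_CLASSES:
            partners = [nv for (v, nv) in cfg.overlap_rule if v == name]
            partner = next((p for p in partners if p in centerlines), None)
            if partner is not None:
                pts = centerlines[partner]
                waypoint = tuple(pts[int(rng.integers(len(pts) // 4, 3 * len(pts) // 4))])
        width_px = rng.uniform(*cfg.tube_width_frac) * min_dim
        if name in NERVE_CLASSES:
            width_px *= 1.25          # nerves render as broader bands
        pts = _spline_points(rng, h, w, cfg.curvature, waypoint)
        centerlines[name] = pts
        footprints[name] = _footprint(pts, h, w, width_px)

    # label composition: nerves, then vessels with composite overlap
    mask = np.zeros((h, w), dtype=np.uint8)
    for name in NERVE_CLASSES:
        if name in footprints:
            mask[footprints[name]] = schema.index_of(name)
    for name in VESSEL_CLASSES:
        if name not in footprints:
            continue
        fp = footprints[name]
        vidx = schema.index_of(name)
        comp = np.zeros_like(fp)
        for (v, nerve), comp_name in cfg.overlap_rule.items():
            if v != name or nerve not in footprints:
                continue
            both = fp & footprints[nerve]
            mask[both] = schema.index_of(comp_name)
            comp |= both
        mask[fp & ~comp] = vidx

    # appearance
    colors = {k: np.asarray(v, dtype=np.float64) for k, v in cfg.colors.items()}
    for (v, nerve), comp_name in cfg.overlap_rule.items():
        colors.setdefault(comp_name, 0.65 * colors[v] + 0.35 * colors[nerve])
    image = np.empty((h, w, 3))
    image[:] = colors["background"]
    image += 18.0 * _smooth_field(rng, h, w)[..., None]
    for idx, abbr, _, _ in schema.entries:
        if idx == 0 or not np.any(mask == idx):
            continue
        tint = colors[abbr] + rng.normal(0, 6, size=3)
        image[mask == idx] = tint
    image *= 1.0 + 0.08 * _smooth_field(rng, h, w)[..., None]

    # endoscope lighting: a few specular highlight blobs
    yy, xx = np.mgrid[0:h, 0:w]
    for _ in range(int(rng.integers(1, 4))):
        cy, cx = rng.uniform(0, h), rng.uniform(0, w)
        s = rng.uniform(0.03, 0.08) * min_dim
        blob = np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * s * s))
        image += cfg.highlight_strength * blob[..., None]

    image += rng.normal(0, cfg.noise_sigma, size=image.shape)
    if cfg.blur_sigma > 0:
        image = ndimage.gaussian_filter(image, sigma=(cfg.blur_sigma, cfg.blur_sigma, 0))
    image = np.clip(image, 0, 255).astype(np.uint8)

    age = AGE_GROUPS[rng.choice(len(AGE_GROUPS), p=np.array(AGE_WEIGHTS) / sum(AGE_WEIGHTS))]
    gender = GENDERS[rng.choice(len(GENDERS), p=np.array(GENDER_WEIGHTS) / sum(GENDER_WEIGHTS))]
    sample = SceneSample(image=image, mask=mask, age_group=age, gender=gender,
                         seed=int(seed))
    if return_geometry:
        return sample, footprints
    return sample


def generate_corpus(cfg: SceneConfig, n_total: int, val_count: int, test_count: int,
                    master_seed: int, out_dir) -> Corpus:
    """Generate ``n_total`` scenes, split them, and write the VOC layout.

    Per-sample seeds derive from ``master_seed``, so two corpora built
    from the same master seed are file-for-file identical.
    """
    schema = LabelSchema.default()
    splits = split_manifest(n_total, val_count, test_count, master_seed)
    split_of = {}
    for name, idxs in splits.items():
        for i in idxs:
            split_of[i] = name
    seeds = np.random.default_rng(master_seed).integers(0, 2 ** 31 - 1, size=n_total)

    def scenes():
        for i in range(n_total):
            s = generate_scene(cfg, int(seeds[i]), schema)
            s.split = split_of[i]
            s.sample_id = f"scene_{i:05d}"
            yield s

    return write_corpus(
        scenes(), out_dir, schema,
        extra_manifest={"master_seed": int(master_seed),
                        "canvas": [cfg.height, cfg.width]},
    )


def smoke_corpus(out_dir, master_seed: int = 7) -> Corpus:
    """The small fixed test fixture: 24 scenes at 128x128 (16/4/4 split)."""
    cfg = SceneConfig(width=128, height=128)
    return generate_corpus(cfg, 24, 4, 4, master_seed, out_dir)
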