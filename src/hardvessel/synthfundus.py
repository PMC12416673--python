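"""Synthetic fundus image simulator.

Generates branching vascular trees inside a bright circular field-of-view
disc on a dark background, renders them as dark curvilinear strokes over a
smooth background gradient with additive Gaussian noise, and writes
DRIVE-style datasets (``images/``, ``manual/``, ``fov/`` + manifest).  The
simulator exists so the whole segmentation pipeline — loader, network, loss,
trainer, metrics — can be exercised end to end without downloading any
retinal dataset.

Geometry model: each of ``n_trees`` roots starts on the FOV rim pointing at
the disc interior.  A segment always continues into one child and spawns a
second (bifurcation) child with probability ``branch_prob``, up to
``max_depth`` generations; widths decay multiplicatively so trunks are
several pixels wide and terminal twigs approach one pixel, mimicking the
trunk-to-capillary range of fundus photographs.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .sample import FundusSample

__all__ = [
    "SimConfig",
    "VesselSegment",
    "VesselTree",
    "generate_tree",
    "render_sample",
    "make_sample",
    "make_dataset",
    "write_dataset",
]

# fixed bifurcation half-angle: children of a branching node leave the
# parent direction at about ±30°, producing Y-junctions
BIFURCATION_ANGLE = np.pi / 6


@dataclass
class SimConfig:
    """Parameters of the vascular-tree simulator (lengths in pixels)."""

    image_height: int = 584
    image_width: int = 565
    n_trees: int = 6
    max_depth: int = 5
    branch_prob: float = 0.35
    initial_width: float = 5.0
    width_decay: float = 0.8
    segment_length: float = 30.0
    angle_jitter: float = 0.22
    vessel_contrast: float = 0.35
    background_level: float = 0.62
    noise_sigma: float = 0.02
    fov_radius_frac: float = 0.94
    seed: int = 0

    def validate(self) -> "SimConfig":
        if self.image_height < 1 or self.image_width < 1:
            raise ValueError("image dimensions must be >= 1 px")
        if self.n_trees < 1 or self.max_depth < 0:
            raise ValueError("n_trees must be >= 1 and max_depth >= 0")
        if not 0.0 <= self.branch_prob <= 1.0:
            raise ValueError("branch_prob must lie in [0,1]")
        if self.initial_width < 1.0:
            raise ValueError("initial_width must be >= 1 px")
        if not 0.0 < self.width_decay <= 1.0:
            raise ValueError("width_decay must lie in (0,1]")
        if not 0.0 < self.fov_radius_frac <= 1.0:
            raise ValueError("fov_radius_frac must lie in (0,1]")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        return self


@dataclass
class VesselSegment:
    start: tuple[float, float]  # (row, col)
    end: tuple[float, float]
    width: float
    depth: int


@dataclass
class VesselTree:
    segments: list[VesselSegment]


def _fov_geometry(config: SimConfig) -> tuple[float, float, float]:
    cy = (config.image_height - 1) / 2.0
    cx = (config.image_width - 1) / 2.0
    radius = config.fov_radius_frac * min(config.image_height,
                                          config.image_width) / 2.0
    return cy, cx, radius


def _grow(segments: list[VesselSegment], rng: np.random.Generator,
          config: SimConfig, start: np.ndarray, angle: float, width: float,
          depth: int) -> None:
    length = config.segment_length * (0.7 + 0.6 * rng.random())
    end = start + length * np.array([np.sin(angle), np.cos(angle)])
    segments.append(VesselSegment(tuple(start), tuple(end), width, depth))
    if depth >= config.max_depth:
        return
    child_width = width * config.width_decay
    # continuation child, always
    cont_angle = angle + rng.normal(0.0, config.angle_jitter)
    branch = rng.random() < config.branch_prob
    if branch:
        side = 1.0 if rng.random() < 0.5 else -1.0
        cont_angle = angle - side * BIFURCATION_ANGLE \
            + rng.normal(0.0, config.angle_jitter)
        branch_angle = angle + side * BIFURCATION_ANGLE \
            + rng.normal(0.0, config.angle_jitter)
    _grow(segments, rng, config, end, cont_angle, child_width, depth + 1)
    if branch:
        _grow(segments, rng, config, end, branch_angle, child_width, depth + 1)


def generate_tree(config: SimConfig, sample_index: int = 0) -> VesselTree:
    """Grow ``config.n_trees`` recursive binary trees from the FOV rim.

    Each tree draws from its own RNG stream seeded by
    ``(config.seed, sample_index, tree_index)``, so adding trees leaves the
    existing ones unchanged and datasets are order-independent.
    """
    config.validate()
    cy, cx, radius = _fov_geometry(config)
    segments: list[VesselSegment] = []
    for tree_index in range(config.n_trees):
        rng = np.random.default_rng(
            [config.seed & 0x7FFFFFFF, sample_index, tree_index])
        theta = rng.uniform(0.0, 2.0 * np.pi)
        start = np.array([cy + 0.98 * radius * np.sin(theta),
                          cx + 0.98 * radius * np.cos(theta)])
        # aim inward: direction of travel points toward the disc centre,
        # perturbed so trees are not all radial
        inward = np.arctan2(cy - start[0], cx - start[1])
        angle = inward + rng.normal(0.0, 2.5 * config.angle_jitter)
        _grow(segments, rng, config, start, angle, config.initial_width, 0)
    return VesselTree(segments=segments)


def _rasterize_segment(mask: np.ndarray, seg: VesselSegment) -> None:
    """Mark pixels whose centre lies within width/2 of the segment."""
    h, w = mask.shape
    radius = seg.width / 2.0
    r0 = max(int(np.floor(min(seg.start[0], seg.end[0]) - radius - 1)), 0)
    r1 = min(int(np.ceil(max(seg.start[0], seg.end[0]) + radius + 1)), h - 1)
    c0 = max(int(np.floor(min(seg.start[1], seg.end[1]) - radius - 1)), 0)
    c1 = min(int(np.ceil(max(seg.start[1], seg.end[1]) + radius + 1)), w - 1)
    if r0 > r1 or c0 > c1:
        return
    rr, cc = np.meshgrid(np.arange(r0, r1 + 1), np.arange(c0, c1 + 1),
                         indexing="ij")
    p = np.stack([rr, cc], axis=-1).astype(np.float64)
    a = np.asarray(seg.start)
    b = np.asarray(seg.end)
    ab = b - a
    denom = float(ab @ ab)
    if denom == 0.0:
        dist = np.linalg.norm(p - a, axis=-1)
    else:
        t = np.clip(((p - a) @ ab) / denom, 0.0, 1.0)
        proj = a + t[..., None] * ab
        dist = np.linalg.norm(p - proj, axis=-1)
    mask[r0:r1 + 1, c0:c1 + 1] |= dist <= radius


def rasterize_tree(tree: VesselTree, shape: tuple[int, int]) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    for seg in tree.segments:
        _rasterize_segment(mask, seg)
    return mask


def render_sample(tree: VesselTree, config: SimConfig,
                  sample_index: int = 0,
                  sample_id: str | None = None) -> FundusSample:
    """Rasterize a tree into an image + vessel mask + FOV mask triple.

    The image is a smooth background gradient at ``background_level`` with
    vessels ``vessel_contrast`` darker (fundus vessels absorb light), plus
    per-channel Gaussian noise; everything outside the FOV disc is near
    black.  The vessel mask is binary by construction and clipped to the
    FOV.
    """
    config.validate()
    h, w = config.image_height, config.image_width
    cy, cx, radius = _fov_geometry(config)
    rr, cc = np.mgrid[0:h, 0:w]
    fov = ((rr - cy) ** 2 + (cc - cx) ** 2) <= radius**2

    vessel = rasterize_tree(tree, (h, w)) & fov

    rng = np.random.default_rng(
        [config.seed & 0x7FFFFFFF, sample_index, 0xBACC])
    # smooth illumination gradient across the disc
    grad_theta = rng.uniform(0.0, 2.0 * np.pi)
    span = max(h, w)
    ramp = ((rr - cy) * np.sin(grad_theta) + (cc - cx) * np.cos(grad_theta)) / span
    gray = config.background_level + 0.08 * ramp
    gray = gray - config.vessel_contrast * vessel

    # mild red dominance as in colour fundus photographs
    channel_scale = np.array([1.0, 0.88, 0.72])
    image = gray[:, :, None] * channel_scale[None, None, :]
    image[~fov] = 0.03
    if config.noise_sigma > 0:
        image = image + rng.normal(0.0, config.noise_sigma, image.shape)
    image = np.clip(image, 0.0, 1.0)

    if sample_id is None:
        sample_id = f"synth_{sample_index:03d}"
    return FundusSample(
        image=image.astype(np.float64),
        vessel_mask=vessel.astype(np.uint8),
        fov_mask=fov.astype(np.uint8),
        native_height=h,
        native_width=w,
        sample_id=sample_id,
        meta={"seed": config.seed, "sample_index": sample_index},
    ).validate()


def make_sample(config: SimConfig, sample_index: int = 0) -> FundusSample:
    return render_sample(generate_tree(config, sample_index), config,
                         sample_index)


def make_dataset(config: SimConfig, n: int,
                 start_index: int = 0) -> list[FundusSample]:
    return [make_sample(config, start_index + i) for i in range(n)]


def write_dataset(samples: list[FundusSample], root_path,
                  force: bool = False) -> dict:
    """Write samples in the DRIVE-like simulator layout.

    ``{root}/images/<id>.png`` (8-bit RGB), ``{root}/manual/<id>.png`` and
    ``{root}/fov/<id>.png`` (8-bit, 0/255), plus ``manifest.json``.
    Refuses to write into an existing non-empty directory unless ``force``.
    """
    if not samples:
        raise ValueError("write_dataset: empty sample list")
    root = Path(root_path)
    if root.exists() and any(root.iterdir()) and not force:
        raise FileExistsError(f"{root} is not empty (use force=True)")
    for sub in ("images", "manual", "fov"):
        (root / sub).mkdir(parents=True, exist_ok=True)
    entries = []
    for s in samples:
        s.validate()
        img8 = np.round(s.image * 255).astype(np.uint8)
        paths = {
            "image": root / "images" / f"{s.sample_id}.png",
            "vessel": root / "manual" / f"{s.sample_id}.png",
            "fov": root / "fov" / f"{s.sample_id}.png",
        }
        iio.imwrite(paths["image"], img8)
        iio.imwrite(paths["vessel"], (s.vessel_mask * 255).astype(np.uint8))
        iio.imwrite(paths["fov"], (s.fov_mask * 255).astype(np.uint8))
        entries.append({
            "id": s.sample_id,
            "image": str(paths["image"].relative_to(root)),
            "vessel": str(paths["vessel"].relative_to(root)),
            "fov": str(paths["fov"].relative_to(root)),
            "height": s.native_height,
            "width": s.native_width,
        })
    manifest = {"layout": "drive_style", "samples": entries}
    (root / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def desk_config(seed: int = 0, size: int = 128, **overrides) -> SimConfig:
    """Desk-scale preset: 128×128 miniatures for fast CPU experiments.

    Vessel geometry is scaled so widths still span the trunk-to-capillary
    range (≈5 px down to ≈2 px) while trees fit the smaller disc.
    """
    base = dict(image_height=size, image_width=size, n_trees=4, max_depth=4,
                branch_prob=0.35, initial_width=5.0, width_decay=0.8,
                segment_length=size * 14.0 / 128.0, angle_jitter=0.22,
                vessel_contrast=0.35, background_level=0.62,
                noise_sigma=0.02, fov_radius_frac=0.94, seed=seed)
    base.update(overrides)
    return SimConfig(**base).validate()


def config_from_dict(d: dict) -> SimConfig:
    known = {k: v for k, v in d.items() if k in SimConfig.__dataclass_fields__}
    return SimConfig(**known).validate()


def config_to_dict(config: SimConfig) -> dict:
    return asdict(config)
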