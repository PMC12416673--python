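"""Loading, preprocessing, geometric normalisation and augmentation.

Images are normalised to [0,1] and optionally histogram-equalised per
channel.  Geometric normalisation to the network's working size (592 for
DRIVE-shaped inputs, 1008 for CHASE-shaped) is centred zero padding with the
offsets recorded, so predictions can be cropped back to native resolution
bit-exactly — padding, unlike interpolation, preserves single-pixel vessels.
Training-time augmentation draws exactly one of four operations per sample:
horizontal flip, vertical flip, contrast adjustment, or additive Gaussian
noise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from skimage.exposure import equalize_hist

from .sample import FundusSample

__all__ = [
    "PadRecord",
    "AugmentChoice",
    "load_sample",
    "normalize",
    "equalize",
    "pad_to",
    "crop_back",
    "split_train_val",
    "augment_random",
    "discover_dataset",
    "load_dataset",
    "AUGMENT_KINDS",
]

AUGMENT_KINDS = ("hflip", "vflip", "contrast", "gaussian_noise")

# unstated magnitudes: mild, label-preserving perturbations
CONTRAST_RANGE = (0.8, 1.2)
NOISE_SIGMA_RANGE = (0.005, 0.03)


@dataclass
class PadRecord:
    """Where a native-size array sits inside its padded canvas."""

    native_height: int
    native_width: int
    target_height: int
    target_width: int
    offset_row: int
    offset_col: int


@dataclass
class AugmentChoice:
    kind: str
    magnitude: float


def _read_array(path) -> np.ndarray:
    arr = np.asarray(iio.imread(path))
    return arr


def _to_unit_float(arr: np.ndarray) -> np.ndarray:
    if arr.dtype == np.uint8:
        return arr.astype(np.float64) / 255.0
    if arr.dtype == np.uint16:
        return arr.astype(np.float64) / 65535.0
    arr = arr.astype(np.float64)
    if arr.max() > 1.0:
        arr = arr / arr.max()
    return arr


def _binarize(arr: np.ndarray) -> np.ndarray:
    """Threshold at half of the dynamic range (handles anti-aliased edges)."""
    arr = arr.astype(np.float64)
    if arr.ndim == 3:
        arr = arr[..., 0]
    lo, hi = float(arr.min()), float(arr.max())
    if hi == lo:
        return (arr > 0).astype(np.uint8)
    return (arr >= (lo + hi) / 2.0).astype(np.uint8)


def load_sample(image_path, vessel_path, fov_path=None,
                sample_id: str | None = None) -> FundusSample:
    """Read an image plus vessel (and optional FOV) annotation from disk."""
    image = _to_unit_float(_read_array(image_path))
    if image.ndim == 2:
        image = np.stack([image] * 3, axis=-1)
    image = image[..., :3]
    h, w = image.shape[:2]

    vessel = _binarize(_read_array(vessel_path))
    if vessel.shape != (h, w):
        raise ValueError(
            f"vessel mask {vessel_path} has shape {vessel.shape}, "
            f"image is {(h, w)}")
    if fov_path is not None:
        fov = _binarize(_read_array(fov_path))
        if fov.shape != (h, w):
            raise ValueError(
                f"FOV mask {fov_path} has shape {fov.shape}, image is {(h, w)}")
    else:
        fov = np.ones((h, w), dtype=np.uint8)
    vessel = vessel & fov
    if sample_id is None:
        sample_id = Path(image_path).stem
    return FundusSample(image=image, vessel_mask=vessel, fov_mask=fov,
                        native_height=h, native_width=w,
                        sample_id=sample_id).validate()


def normalize(image: np.ndarray) -> np.ndarray:
    """Per-image min-max scaling to [0,1]; a constant image maps to zeros."""
    image = np.asarray(image, dtype=np.float64)
    lo, hi = float(image.min()), float(image.max())
    if hi == lo:
        return np.zeros_like(image)
    return (image - lo) / (hi - lo)


def equalize(image: np.ndarray, nbins: int = 256) -> np.ndarray:
    """Histogram equalisation, per channel, output in [0,1]."""
    image = np.asarray(image, dtype=np.float64)
    if image.ndim == 2:
        return equalize_hist(image, nbins=nbins)
    out = np.empty_like(image)
    for c in range(image.shape[2]):
        out[..., c] = equalize_hist(image[..., c], nbins=nbins)
    return out


def pad_to(sample: FundusSample, target_h: int, target_w: int
           ) -> tuple[FundusSample, PadRecord]:
    """Centre the sample on a zero canvas of the target size."""
    h, w = sample.native_height, sample.native_width
    if target_h < h or target_w < w:
        raise ValueError(
            f"pad_to target {(target_h, target_w)} smaller than native {(h, w)}")
    off_r = (target_h - h) // 2
    off_c = (target_w - w) // 2
    record = PadRecord(h, w, target_h, target_w, off_r, off_c)

    def place(arr, channels=False):
        shape = (target_h, target_w) + arr.shape[2:]
        canvas = np.zeros(shape, dtype=arr.dtype)
        canvas[off_r:off_r + h, off_c:off_c + w] = arr
        return canvas

    padded = FundusSample(
        image=place(sample.image),
        vessel_mask=place(sample.vessel_mask),
        fov_mask=place(sample.fov_mask),
        native_height=h,
        native_width=w,
        sample_id=sample.sample_id,
        meta=dict(sample.meta),
    )
    return padded, record


def crop_back(arr: np.ndarray, record: PadRecord) -> np.ndarray:
    """Recover the native-resolution window recorded at padding time."""
    if arr.shape[:2] != (record.target_height, record.target_width):
        raise ValueError(
            f"crop_back: array shape {arr.shape[:2]} does not match the pad "
            f"record target {(record.target_height, record.target_width)}")
    return arr[record.offset_row:record.offset_row + record.native_height,
               record.offset_col:record.offset_col + record.native_width]


def split_train_val(sample_ids: list[str], ratio: float = 0.9
                    ) -> tuple[list[str], list[str]]:
    """Deterministic 9:1-style split on the sorted id list."""
    ids = sorted(sample_ids)
    if len(ids) != len(set(ids)):
        raise ValueError("sample ids must be unique")
    if len(ids) < 2:
        raise ValueError("need at least 2 samples to split")
    n_train = int(np.floor(ratio * len(ids)))
    n_train = min(max(n_train, 1), len(ids) - 1)
    return ids[:n_train], ids[n_train:]


def augment_random(sample: FundusSample, rng: np.random.Generator
                   ) -> tuple[FundusSample, AugmentChoice]:
    """Apply exactly one randomly chosen augmentation.

    Flips act on image and both masks alike; contrast and noise act on the
    image only (labels are geometry, not intensity).
    """
    kind = AUGMENT_KINDS[rng.integers(len(AUGMENT_KINDS))]
    image = sample.image
    vessel = sample.vessel_mask
    fov = sample.fov_mask
    magnitude = 0.0
    if kind == "hflip":
        image = image[:, ::-1].copy()
        vessel = vessel[:, ::-1].copy()
        fov = fov[:, ::-1].copy()
        magnitude = 1.0
    elif kind == "vflip":
        image = image[::-1].copy()
        vessel = vessel[::-1].copy()
        fov = fov[::-1].copy()
        magnitude = 1.0
    elif kind == "contrast":
        magnitude = rng.uniform(*CONTRAST_RANGE)
        mean = image.mean()
        image = np.clip(mean + magnitude * (image - mean), 0.0, 1.0)
    else:  # gaussian_noise
        magnitude = rng.uniform(*NOISE_SIGMA_RANGE)
        image = np.clip(image + rng.normal(0.0, magnitude, image.shape),
                        0.0, 1.0)
    out = FundusSample(image=image, vessel_mask=vessel, fov_mask=fov,
                       native_height=sample.native_height,
                       native_width=sample.native_width,
                       sample_id=sample.sample_id, meta=dict(sample.meta))
    return out, AugmentChoice(kind=kind, magnitude=magnitude)


# ---------------------------------------------------------------------------
# dataset discovery: simulator layout and DRIVE-style trees
# ---------------------------------------------------------------------------

def discover_dataset(root_path) -> list[dict]:
    """Pair image/vessel/FOV files under ``root_path``.

    Understands the simulator layout (``images/ manual/ fov/`` +
    ``manifest.json``) and the DRIVE convention
    (``images/ 1st_manual/ mask/``), pairing files by sorted stem order.
    """
    root = Path(root_path)
    manifest = root / "manifest.json"
    if manifest.exists():
        data = json.loads(manifest.read_text())
        return [
            {"id": e["id"], "image": root / e["image"],
             "vessel": root / e["vessel"],
             "fov": root / e["fov"] if e.get("fov") else None}
            for e in data["samples"]
        ]
    img_dir = root / "images"
    if not img_dir.is_dir():
        raise FileNotFoundError(f"no images/ directory under {root}")
    vessel_dir = next((root / d for d in ("manual", "1st_manual")
                       if (root / d).is_dir()), None)
    if vessel_dir is None:
        raise FileNotFoundError(f"no manual/ or 1st_manual/ under {root}")
    fov_dir = next((root / d for d in ("fov", "mask")
                    if (root / d).is_dir()), None)
    images = sorted(p for p in img_dir.iterdir() if p.is_file())
    vessels = sorted(p for p in vessel_dir.iterdir() if p.is_file())
    fovs = sorted(p for p in fov_dir.iterdir() if p.is_file()) \
        if fov_dir else [None] * len(images)
    if not (len(images) == len(vessels) == len(fovs)):
        raise ValueError(
            f"unpaired dataset under {root}: {len(images)} images, "
            f"{len(vessels)} vessel masks, {len(fovs)} FOV masks")
    return [{"id": i.stem, "image": i, "vessel": v, "fov": f}
            for i, v, f in zip(images, vessels, fovs)]


def load_dataset(root_path) -> list[FundusSample]:
    return [load_sample(e["image"], e["vessel"], e["fov"], sample_id=e["id"])
            for e in discover_dataset(root_path)]
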