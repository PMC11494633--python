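"""Dataset I/O, preprocessing, and the synthetic spike-field generator.

On-disk annotation format is YOLO labels (one ``.txt`` per image, lines of
``class cx cy w h`` normalized to image size).  The synthetic generator
renders textured, elongated, rotated ellipses ("spikes") over a textured
background with controlled pairwise overlap, three altitude-scale regimes
(emulating 7/12/20 m UAV capture heights), and per-image illumination
variation.  Every scene is a pure function of its seed.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml
from PIL import Image

from .geometry import Box

__all__ = [
    "ImageSample",
    "SceneSpec",
    "LetterboxTransform",
    "read_yolo_labels",
    "write_yolo_labels",
    "letterbox",
    "generate_scene",
    "make_benchmark",
    "load_benchmark",
    "ALTITUDE_SCALE",
]

# altitude regime -> spike size multiplier (lower flight = bigger spikes)
ALTITUDE_SCALE = {"7m": 1.6, "12m": 1.0, "20m": 0.6}


@dataclass
class ImageSample:
    image: np.ndarray  # (H, W, 3) uint8
    labels: list[tuple[int, Box]]
    source_id: str = ""
    altitude: str | None = None
    meta: dict = field(default_factory=dict)

    @property
    def size(self) -> tuple[int, int]:
        """(width, height)"""
        return (self.image.shape[1], self.image.shape[0])


@dataclass
class SceneSpec:
    """Parameters of one synthetic spike-field image."""

    image_size: tuple[int, int] = (96, 96)  # (width, height)
    count: tuple[int, int] = (6, 12)  # uniform-integer spike count range
    length: tuple[float, float] = (18.0, 30.0)  # spike major axis, px (12 m regime)
    aspect: tuple[float, float] = (0.28, 0.45)  # minor/major axis ratio
    altitude: str = "12m"
    overlap_frac: float = 0.35  # fraction of spikes placed overlapping a prior one
    overlap_iou: float = 0.3  # target box IoU for those placements
    gain: tuple[float, float] = (0.75, 1.2)  # illumination gain range
    gamma: tuple[float, float] = (0.8, 1.25)  # illumination gamma range
    bg_smooth: int = 7  # background texture smoothing kernel
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.overlap_frac < 1.0 and 0.0 <= self.overlap_iou < 1.0):
            raise ValueError("overlap fractions must lie in [0, 1)")
        if self.altitude not in ALTITUDE_SCALE:
            raise ValueError(f"altitude must be one of {sorted(ALTITUDE_SCALE)}")
        w, h = self.image_size
        max_len = self.length[1] * ALTITUDE_SCALE[self.altitude]
        if max_len >= min(w, h) - 4:
            raise ValueError(
                "infeasible spec: max spike length must be < image side - 4; "
                "reduce length, altitude scale, or enlarge the image"
            )


# -- YOLO label I/O ----------------------------------------------------------


def read_yolo_labels(path: str | Path, image_size: tuple[int, int]) -> list[tuple[int, Box]]:
    """Read normalized ``class cx cy w h`` lines into pixel-space boxes."""
    w, h = image_size
    out: list[tuple[int, Box]] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 5:
                raise ValueError(f"{path}:{ln}: expected 5 columns, got {len(parts)}")
            try:
                cid = int(parts[0])
                cx, cy, bw, bh = (float(p) for p in parts[1:])
            except ValueError as e:
                raise ValueError(f"{path}:{ln}: malformed number ({e})") from None
            if not all(0.0 <= v <= 1.0 for v in (cx, cy, bw, bh)):
                raise ValueError(f"{path}:{ln}: normalized values outside [0,1]")
            out.append((cid, Box.from_xywh(cx * w, cy * h, bw * w, bh * h)))
    return out


def write_yolo_labels(
    path: str | Path, labels: list[tuple[int, Box]], image_size: tuple[int, int]
) -> None:
    w, h = image_size
    lines = []
    for cid, b in labels:
        xc, yc, bw, bh = b.to_xywh()
        lines.append(f"{cid} {xc / w:.6f} {yc / h:.6f} {bw / w:.6f} {bh / h:.6f}")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


# -- letterbox ---------------------------------------------------------------


@dataclass(frozen=True)
class LetterboxTransform:
    scale: float
    pad_x: float
    pad_y: float

    def apply_box(self, b: Box) -> Box:
        s, px, py = self.scale, self.pad_x, self.pad_y
        return Box(b.x1 * s + px, b.y1 * s + py, b.x2 * s + px, b.y2 * s + py)

    def invert_box(self, b: Box) -> Box:
        s, px, py = self.scale, self.pad_x, self.pad_y
        return Box((b.x1 - px) / s, (b.y1 - py) / s, (b.x2 - px) / s, (b.y2 - py) / s)


def letterbox(
    image: np.ndarray, target: int = 640, fill: int = 114
) -> tuple[np.ndarray, LetterboxTransform]:
    """Aspect-preserving resize of the longest side to ``target`` plus
    even constant padding to a square; returns the exact affine."""
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[0] == 0 or img.shape[1] == 0:
        raise ValueError("letterbox needs a non-empty HxWx3 image")
    h, w = img.shape[:2]
    scale = target / max(h, w)
    nw, nh = round(w * scale), round(h * scale)
    if (nw, nh) != (w, h):
        resized = np.asarray(
            Image.fromarray(img).resize((nw, nh), resample=Image.BILINEAR)
        )
    else:
        resized = img
    out = np.full((target, target, img.shape[2]), fill, dtype=img.dtype)
    px = (target - nw) // 2
    py = (target - nh) // 2
    out[py : py + nh, px : px + nw] = resized
    return out, LetterboxTransform(scale=scale, pad_x=float(px), pad_y=float(py))


# -- synthetic scene generation ----------------------------------------------


def _smooth(arr: np.ndarray, k: int) -> np.ndarray:
    """Separable box smoothing (edge-padded), k odd."""
    from scipy.ndimage import uniform_filter

    return uniform_filter(arr, size=(k, k, 1) if arr.ndim == 3 else k, mode="nearest")


def _ellipse_mask(
    w: int, h: int, cx: float, cy: float, a: float, b: float, theta: float
) -> np.ndarray:
    yy, xx = np.mgrid[0:h, 0:w]
    dx = xx + 0.5 - cx
    dy = yy + 0.5 - cy
    ct, st = np.cos(theta), np.sin(theta)
    u = (dx * ct + dy * st) / a
    v = (-dx * st + dy * ct) / b
    return (u * u + v * v) <= 1.0


def _ellipse_extents(a: float, b: float, theta: float) -> tuple[float, float]:
    """Half-extents of the axis-aligned bbox of a rotated ellipse."""
    ct, st = np.cos(theta), np.sin(theta)
    ex = np.sqrt((a * ct) ** 2 + (b * st) ** 2)
    ey = np.sqrt((a * st) ** 2 + (b * ct) ** 2)
    return float(ex), float(ey)


def _solve_offset_for_iou(wa: float, ha: float, wb: float, hb: float, target: float) -> float:
    """Distance (along x, centres level in y) between two axis-aligned boxes
    of sizes (wa,ha),(wb,hb) so their IoU is ``target``; bisection."""

    def iou_at(d: float) -> float:
        iw = max(min(wa, wb, (wa + wb) / 2 - d), 0.0)
        ih = min(ha, hb)
        inter = iw * ih
        return inter / (wa * ha + wb * hb - inter)

    lo, hi = 0.0, (wa + wb) / 2
    if iou_at(0.0) <= target:
        return 0.0
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if iou_at(mid) > target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def generate_scene(spec: SceneSpec) -> ImageSample:
    """Render one deterministic synthetic spike-field image with exact
    mask-tight bounding boxes."""
    rng = np.random.default_rng(spec.seed)
    w, h = spec.image_size
    mult = ALTITUDE_SCALE[spec.altitude]

    # background: smoothed soil/canopy noise in greens and browns
    base = np.array([62.0, 86.0, 48.0])  # dark canopy green
    bg = base[None, None, :] + rng.normal(0.0, 26.0, size=(h, w, 3))
    bg = _smooth(bg, spec.bg_smooth)
    bg += rng.normal(0.0, 5.0, size=(h, w, 3))  # fine grain
    img = bg

    # illumination drawn before spike placement so it is independent of count
    gain = rng.uniform(*spec.gain)
    gamma = rng.uniform(*spec.gamma)

    n = int(rng.integers(spec.count[0], spec.count[1] + 1))
    labels: list[tuple[int, Box]] = []
    placed: list[tuple[float, float, float, float]] = []  # cx, cy, ex, ey
    overlap_log: list[float] = []

    for i in range(n):
        length = rng.uniform(*spec.length) * mult
        a = length / 2.0
        b = a * rng.uniform(*spec.aspect)
        theta = rng.uniform(0.0, np.pi)
        ex, ey = _ellipse_extents(a, b, theta)
        margin_x, margin_y = ex + 1.0, ey + 1.0
        if 2 * margin_x >= w or 2 * margin_y >= h:
            raise ValueError("infeasible spec: spike larger than image; shrink length")

        cx = cy = None
        if placed and rng.random() < spec.overlap_frac:
            # deliberate overlap with a random prior spike at the target IoU
            acx, acy, aex, aey = placed[int(rng.integers(len(placed)))]
            horizontal = rng.random() < 0.5
            sign = 1.0 if rng.random() < 0.5 else -1.0
            if horizontal:
                d = _solve_offset_for_iou(2 * aex, 2 * aey, 2 * ex, 2 * ey, spec.overlap_iou)
                cx, cy = acx + sign * d, acy
            else:
                d = _solve_offset_for_iou(2 * aey, 2 * aex, 2 * ey, 2 * ex, spec.overlap_iou)
                cx, cy = acx, acy + sign * d
            if not (margin_x <= cx <= w - margin_x and margin_y <= cy <= h - margin_y):
                cx = cy = None  # fell outside: fall back to free placement
        if cx is None:
            cx = rng.uniform(margin_x, w - margin_x)
            cy = rng.uniform(margin_y, h - margin_y)

        mask = _ellipse_mask(w, h, cx, cy, a, b, theta)
        if not mask.any():
            continue
        # spike texture: golden tone, kernel stripes along the major axis
        yy, xx = np.nonzero(mask)
        u = (xx + 0.5 - cx) * np.cos(theta) + (yy + 0.5 - cy) * np.sin(theta)
        tone = np.array([196.0, 172.0, 96.0]) * rng.uniform(0.85, 1.1)
        stripes = 18.0 * np.sin(u * (2 * np.pi / max(3.0, b * 1.6)))
        grain = rng.normal(0.0, 7.0, size=(len(xx), 3))
        img[yy, xx, :] = tone[None, :] + stripes[:, None] + grain

        # exact, mask-tight box (pixel-cover convention)
        x1, x2 = xx.min(), xx.max() + 1
        y1, y2 = yy.min(), yy.max() + 1
        box = Box(float(x1), float(y1), float(x2), float(y2))
        if placed:
            from .geometry import iou_matrix

            prev = np.array(
                [(pcx - pex, pcy - pey, pcx + pex, pcy + pey) for pcx, pcy, pex, pey in placed]
            )
            best = float(iou_matrix(np.array([box.to_xyxy()]), prev).max())
            if best > 0:
                overlap_log.append(best)
        labels.append((0, box))
        placed.append((cx, cy, ex, ey))

    # per-image illumination: gain and gamma on the whole frame
    img = np.clip(img * gain, 0.0, 255.0)
    img = 255.0 * (img / 255.0) ** gamma
    image = np.clip(img, 0, 255).astype(np.uint8)
    return ImageSample(
        image=image,
        labels=labels,
        source_id=f"scene-{spec.seed}",
        altitude=spec.altitude,
        meta={"overlap_log": overlap_log, "n_requested": n},
    )


# -- benchmark dataset -------------------------------------------------------


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def make_benchmark(
    out_dir: str | Path,
    n_train: int,
    n_val: int,
    spec_family: SceneSpec | None = None,
    seed: int = 0,
    force: bool = False,
) -> Path:
    """Write a stratified synthetic benchmark: PNG images, YOLO labels and
    a YAML manifest with per-file checksums.  The three altitude regimes
    are balanced within each split (counts within 1 of n/3)."""
    if n_train <= 0 or n_val <= 0:
        raise ValueError("split sizes must be positive")
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise FileExistsError(f"{out} is not empty; pass force=True to overwrite")
    base = spec_family or SceneSpec()
    regimes = sorted(ALTITUDE_SCALE)
    manifest: dict = {"seed": seed, "image_size": list(base.image_size), "splits": {}}
    idx = 0
    for split, count in (("train", n_train), ("val", n_val)):
        img_dir = out / "images" / split
        lbl_dir = out / "labels" / split
        img_dir.mkdir(parents=True, exist_ok=True)
        lbl_dir.mkdir(parents=True, exist_ok=True)
        entries = []
        for k in range(count):
            altitude = regimes[k % len(regimes)]
            spec = replace(base, altitude=altitude, seed=seed * 1_000_003 + idx)
            sample = generate_scene(spec)
            name = f"{split}_{k:04d}"
            img_path = img_dir / f"{name}.png"
            lbl_path = lbl_dir / f"{name}.txt"
            Image.fromarray(sample.image).save(img_path)
            write_yolo_labels(lbl_path, sample.labels, sample.size)
            entries.append(
                {
                    "image": str(img_path.relative_to(out)),
                    "labels": str(lbl_path.relative_to(out)),
                    "altitude": altitude,
                    "n_boxes": len(sample.labels),
                    "sha256_image": _sha256(img_path),
                    "sha256_labels": _sha256(lbl_path),
                }
            )
            idx += 1
        manifest["splits"][split] = entries
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return out / "manifest.yaml"


def load_benchmark(manifest_path: str | Path) -> dict[str, list[ImageSample]]:
    """Load a benchmark written by :func:`make_benchmark` back into memory."""
    manifest_path = Path(manifest_path)
    root = manifest_path.parent
    with open(manifest_path) as fh:
        manifest = yaml.safe_load(fh)
    out: dict[str, list[ImageSample]] = {}
    for split, entries in manifest["splits"].items():
        samples = []
        for e in entries:
            img = np.asarray(Image.open(root / e["image"]).convert("RGB"))
            size = (img.shape[1], img.shape[0])
            labels = read_yolo_labels(root / e["labels"], size)
            samples.append(
                ImageSample(
                    image=img,
                    labels=labels,
                    source_id=e["image"],
                    altitude=e.get("altitude"),
                )
            )
        out[split] = samples
    return out


# -- minimal augmentation (off by default) -----------------------------------


def hflip(sample: ImageSample) -> ImageSample:
    w = sample.image.shape[1]
    flipped = sample.image[:, ::-1].copy()
    labels = [(c, Box(w - b.x2, b.y1, w - b.x1, b.y2)) for c, b in sample.labels]
    return ImageSample(flipped, labels, sample.source_id, sample.altitude, dict(sample.meta))


def hsv_jitter(sample: ImageSample, rng: np.random.Generator, strength: float = 0.2) -> ImageSample:
    gain = 1.0 + rng.uniform(-strength, strength, size=3)
    img = np.clip(sample.image.astype(np.float32) * gain[None, None, :], 0, 255).astype(np.uint8)
    return ImageSample(img, list(sample.labels), sample.source_id, sample.altitude, dict(sample.meta))
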