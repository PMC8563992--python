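"""Synthetic nadir field scenes with exact ground truth.

Renders UAV-like RGB images of freshly transplanted paddies: each rice
cluster (hill) is a tuft of narrow light-yellow blades radiating from its
planting position, on a dark-soil background, optionally with bright
high-blue "bubble" blobs (standing-water reflections) and isolated
foreground-coloured speckle noise.

The colour samplers are constructed so that blade pixels always satisfy the
detection colour rule ((R+G)/2 > 220 and B < 200), soil always fails the
first clause, and bubbles pass the first clause but fail the second via
B >= 200 — so every branch of the binarisation is exercised.  Geometry is
deliberately schematic (no shadows, perspective or radiometric effects);
the value of the scene is its exact, machine-readable ground truth.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

import numpy as np
from skimage.draw import disk as draw_disk
from skimage.draw import line as draw_line

from .detection import ClusterSet, RGBImage
from .errors import InvalidInputError, InvalidParameterError, ParseError

__all__ = [
    "SceneSpec",
    "GroundTruth",
    "render_scene",
    "write_ground_truth",
    "read_ground_truth",
]


def sample_foreground(rng: np.random.Generator, n: int) -> np.ndarray:
    """Seedling colours: (R+G)/2 > 220 and B < 200 always hold."""
    r = rng.integers(235, 256, n)
    g = rng.integers(228, 253, n)
    b = rng.integers(90, 161, n)
    return np.column_stack([r, g, b]).astype(np.uint8)


def sample_soil(rng: np.random.Generator, n: int) -> np.ndarray:
    """Wet-soil colours: (R+G)/2 <= 220 always (rule clause 1 fails)."""
    r = rng.integers(70, 131, n)
    g = rng.integers(55, 111, n)
    b = rng.integers(35, 91, n)
    return np.column_stack([r, g, b]).astype(np.uint8)


def sample_bubble(rng: np.random.Generator, n: int) -> np.ndarray:
    """Bubble colours: bright like seedlings but with B >= 200 (clause 2 fails)."""
    r = rng.integers(225, 256, n)
    g = rng.integers(225, 256, n)
    b = rng.integers(200, 256, n)
    return np.column_stack([r, g, b]).astype(np.uint8)


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one rendered scene.

    ``positions_cm`` holds ground coordinates (x_cm, y_cm); the pixel mapping
    is col = x/gsd, row = y/gsd.  Densities are blob/pixel counts per
    megapixel of image area.
    """

    width: int
    height: int
    positions_cm: np.ndarray
    gsd: float = 0.2
    blades_per_cluster: int = 5
    blade_length: int = 18
    angle_jitter: float = 0.15
    bubble_density: float = 20.0
    bubble_radius: tuple[int, int] = (2, 6)
    speckle_density: float = 300.0
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(
            self, "positions_cm", np.asarray(self.positions_cm, dtype=float).reshape(-1, 2)
        )
        if self.width < 1 or self.height < 1:
            raise InvalidParameterError("image must be at least 1 x 1")
        if self.gsd <= 0:
            raise InvalidParameterError("gsd must be positive")
        if self.blades_per_cluster < 1 or self.blade_length < 1:
            raise InvalidParameterError("blade geometry must be positive")


@dataclass(frozen=True)
class GroundTruth:
    """Exact cluster positions of a rendered scene, in pixels and centimetres."""

    ids: np.ndarray
    rows_px: np.ndarray
    cols_px: np.ndarray
    x_cm: np.ndarray
    y_cm: np.ndarray
    pixel_counts: np.ndarray
    gsd: float

    def __len__(self) -> int:
        return len(self.ids)

    def to_cluster_set(self) -> ClusterSet:
        pos = np.column_stack([self.rows_px, self.cols_px])
        return ClusterSet(pos, gsd=self.gsd, provenance="ground_truth", units="px")

    def __eq__(self, other) -> bool:
        if not isinstance(other, GroundTruth):
            return NotImplemented
        return self.gsd == other.gsd and all(
            np.array_equal(getattr(self, f), getattr(other, f))
            for f in ("ids", "rows_px", "cols_px", "x_cm", "y_cm", "pixel_counts")
        )


def _blade_pixels(rng, r0: float, c0: float, spec: SceneSpec, h: int, w: int) -> set:
    """Pixel set of one cluster: blades at evenly spaced, jittered angles."""
    pix: set[tuple[int, int]] = set()
    k = spec.blades_per_cluster
    base = rng.uniform(0.0, 2 * np.pi)
    for m in range(k):
        ang = base + 2 * np.pi * m / k + spec.angle_jitter * rng.standard_normal()
        dr, dc = np.sin(ang), np.cos(ang)
        r1 = r0 + spec.blade_length * dr
        c1 = c0 + spec.blade_length * dc
        # three parallel lines give the blade ~3 px of width
        for off in (-1, 0, 1):
            pr, pc = -dc * off, dr * off
            rr, cc = draw_line(
                int(round(r0 + pr)), int(round(c0 + pc)),
                int(round(r1 + pr)), int(round(c1 + pc)),
            )
            for r, c in zip(rr, cc):
                if 0 <= r < h and 0 <= c < w:
                    pix.add((int(r), int(c)))
    return pix


def render_scene(spec: SceneSpec) -> tuple[RGBImage, GroundTruth]:
    """Render the scene; deterministic under the spec's seed."""
    h, w = spec.height, spec.width
    rows = spec.positions_cm[:, 1] / spec.gsd
    cols = spec.positions_cm[:, 0] / spec.gsd
    bad = np.nonzero((rows < 0) | (rows >= h) | (cols < 0) | (cols >= w))[0]
    if len(bad):
        raise InvalidInputError(
            "positions outside the image at this gsd: " + ", ".join(map(str, bad))
        )

    rng = np.random.default_rng(spec.seed)
    img = np.empty((h, w, 3), dtype=np.uint8)
    img.reshape(-1, 3)[:] = sample_soil(rng, h * w)

    mp = h * w / 1e6
    n_bubbles = int(round(spec.bubble_density * mp))
    for _ in range(n_bubbles):
        cr = rng.integers(0, h)
        cc = rng.integers(0, w)
        rad = int(rng.integers(spec.bubble_radius[0], spec.bubble_radius[1] + 1))
        rr, ccx = draw_disk((int(cr), int(cc)), rad, shape=(h, w))
        img[rr, ccx] = sample_bubble(rng, len(rr))

    n_speckle = int(round(spec.speckle_density * mp))
    if n_speckle:
        sr = rng.integers(0, h, n_speckle)
        sc = rng.integers(0, w, n_speckle)
        img[sr, sc] = sample_foreground(rng, n_speckle)

    counts = np.zeros(len(rows), dtype=int)
    for i, (r0, c0) in enumerate(zip(rows, cols)):
        pix = _blade_pixels(rng, r0, c0, spec, h, w)
        counts[i] = len(pix)
        if pix:
            idx = np.array(sorted(pix))
            img[idx[:, 0], idx[:, 1]] = sample_foreground(rng, len(idx))

    gt = GroundTruth(
        ids=np.arange(len(rows)),
        rows_px=rows.copy(),
        cols_px=cols.copy(),
        x_cm=spec.positions_cm[:, 0].copy(),
        y_cm=spec.positions_cm[:, 1].copy(),
        pixel_counts=counts,
        gsd=spec.gsd,
    )
    return RGBImage(img, gsd=spec.gsd), gt


_GT_HEADER = ["id", "row_px", "col_px", "x_cm", "y_cm", "pixel_count"]


def write_ground_truth(gt: GroundTruth, path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_GT_HEADER + ["gsd"])
        for k in range(len(gt)):
            writer.writerow(
                [int(gt.ids[k]), repr(float(gt.rows_px[k])), repr(float(gt.cols_px[k])),
                 repr(float(gt.x_cm[k])), repr(float(gt.y_cm[k])),
                 int(gt.pixel_counts[k]), repr(float(gt.gsd))]
            )


def read_ground_truth(path) -> GroundTruth:
    ids, rows, cols, xs, ys, counts = [], [], [], [], [], []
    gsd = None
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError("empty file", line=1) from None
        if [h.strip() for h in header[:6]] != _GT_HEADER:
            raise ParseError(f"expected header {','.join(_GT_HEADER)}", line=1)
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            try:
                ids.append(int(row[0]))
                rows.append(float(row[1]))
                cols.append(float(row[2]))
                xs.append(float(row[3]))
                ys.append(float(row[4]))
                counts.append(int(row[5]))
                if len(row) > 6:
                    gsd = float(row[6])
            except (ValueError, IndexError) as exc:
                raise ParseError(str(exc), line=lineno) from None
    return GroundTruth(
        ids=np.array(ids, dtype=int),
        rows_px=np.array(rows, dtype=float),
        cols_px=np.array(cols, dtype=float),
        x_cm=np.array(xs, dtype=float),
        y_cm=np.array(ys, dtype=float),
        pixel_counts=np.array(counts, dtype=int),
        gsd=gsd if gsd is not None else 0.2,
    )
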