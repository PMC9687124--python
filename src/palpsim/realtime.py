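"""Real-time serving: corner-force rows -> palpation input -> stress frames.

Software stand-in for the projector platform: a 400 mm x 400 mm force
plate with one force sensor per corner.  The palpation position is the
force-weighted centroid of the corner coordinates (static moment
balance), the total force the sum of the corner readings.  Each reading
is fed to the trained surrogate and the predicted liver-edge stress
field is rendered as a colour-mapped plan-view image with an embedded
colour bar.
"""

from __future__ import annotations

import csv
import logging
import time as _time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from matplotlib import colormaps
from PIL import Image

from .phantom import HexMesh
from .surrogate import SurrogateModel, predict

__all__ = [
    "PlatformGeometry",
    "RenderSpec",
    "SensorFaultError",
    "resolve_contact",
    "split_corner_forces",
    "make_render_spec",
    "render_frame",
    "serve",
    "synthesize_gesture",
]

logger = logging.getLogger(__name__)


class SensorFaultError(RuntimeError):
    """A corner sensor reported a negative force beyond tolerance."""


@dataclass(frozen=True)
class PlatformGeometry:
    """Force plate with four corner sensors (coordinates in mm)."""

    width: float = 400.0
    height: float = 400.0
    corners: tuple[tuple[float, float], ...] = ()

    def __post_init__(self) -> None:
        if not self.corners:
            object.__setattr__(
                self,
                "corners",
                ((0.0, 0.0), (self.width, 0.0), (self.width, self.height), (0.0, self.height)),
            )
        if len({tuple(c) for c in self.corners}) != 4:
            raise ValueError("platform needs four distinct corner sensors")

    @property
    def corner_array(self) -> np.ndarray:
        return np.asarray(self.corners, dtype=float)


def resolve_contact(
    corner_forces,
    geometry: PlatformGeometry,
    noise_threshold: float = 0.5,
    negative_tolerance: float = 0.5,
):
    """(x, y, total force) from the four corner readings, or None.

    Total force is the sum of the corner forces; the contact position is
    their force-weighted centroid (static moment balance about both
    plate axes).  A total below ``noise_threshold`` N means no contact.
    A corner more negative than ``negative_tolerance`` flags a sensor
    fault.
    """
    f = np.asarray(corner_forces, dtype=float)
    if f.shape != (4,):
        raise ValueError("expected four corner forces")
    if np.any(f < -negative_tolerance):
        raise SensorFaultError(f"negative corner force {f.min():.3f} N beyond tolerance")
    total = float(f.sum())
    if total < noise_threshold:
        return None
    pos = f @ geometry.corner_array / total
    return float(pos[0]), float(pos[1]), total


def split_corner_forces(x: float, y: float, force: float, geometry: PlatformGeometry) -> np.ndarray:
    """Synthetic inverse of resolve_contact: bilinear force split.

    Distributes ``force`` over the four corners with bilinear weights so
    the force-weighted centroid is exactly (x, y) for points inside the
    plate.
    """
    u = x / geometry.width
    v = y / geometry.height
    if not (0.0 <= u <= 1.0 and 0.0 <= v <= 1.0):
        raise ValueError("position outside the plate")
    w = np.array([(1 - u) * (1 - v), u * (1 - v), u * v, (1 - u) * v])
    return force * w


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------


@dataclass
class RenderSpec:
    """Colour-mapped plan-view rendering of the ROI stress field.

    ``footprints`` maps each ROI element to its pixel rectangle
    (row0, row1, col0, col1) in the image; every element covers at least
    one pixel.  Values are clamped to [vmin, vmax]; the diverging colour
    map is anchored so that vmin/vmax hit its end colours.
    """

    vmin: float
    vmax: float
    image_size: tuple[int, int]  # (width, height) px
    footprints: np.ndarray  # (roi, 4) int
    colormap: str = "RdBu_r"
    colorbar_px: int = 24
    background: tuple[int, int, int] = (235, 235, 235)

    def __post_init__(self) -> None:
        if not self.vmin < self.vmax:
            raise ValueError("display range needs vmin < vmax")
        if np.any((self.footprints[:, 1] <= self.footprints[:, 0]) | (self.footprints[:, 3] <= self.footprints[:, 2])):
            raise ValueError("every ROI element must map to at least one pixel")


def make_render_spec(
    mesh: HexMesh,
    value_range: tuple[float, float],
    image_size: tuple[int, int] = (400, 300),
    colormap: str = "RdBu_r",
) -> RenderSpec:
    """Build the ROI-element -> pixel footprint map from the mesh plan view.

    The mesh's plan-view (x-y) bounding box is scaled to the image; each
    ROI element's top-face plan square becomes a pixel rectangle (rows
    run top of image = max y).
    """
    roi = mesh.roi_elements
    if len(roi) == 0:
        raise ValueError("mesh has no tagged ROI elements")
    wpx, hpx = image_size
    draw_w = wpx - 2 * 24  # leave room for the colour bar strip + margin
    xy = mesh.node_coords[:, :2]
    lo, hi = xy.min(axis=0), xy.max(axis=0)
    span = np.where(hi > lo, hi - lo, 1.0)
    foots = np.zeros((len(roi), 4), dtype=int)
    for i, eid in enumerate(roi):
        pts = mesh.node_coords[mesh.elements[eid]][:, :2]
        u0, v0 = (pts.min(axis=0) - lo) / span
        u1, v1 = (pts.max(axis=0) - lo) / span
        c0, c1 = int(u0 * draw_w), max(int(u1 * draw_w), int(u0 * draw_w) + 1)
        r0, r1 = int((1 - v1) * (hpx - 1)), max(int((1 - v0) * (hpx - 1)), int((1 - v1) * (hpx - 1)) + 1)
        foots[i] = (r0, r1, c0, c1)
    return RenderSpec(
        vmin=float(value_range[0]),
        vmax=float(value_range[1]),
        image_size=image_size,
        footprints=foots,
        colormap=colormap,
    )


def render_frame(sigma3: np.ndarray, spec: RenderSpec) -> Image.Image:
    """Colour-mapped image of one ROI stress vector.

    Pure function of (vector, spec): identical inputs give byte-identical
    images.  Values beyond the display range clamp to the end colours; a
    vertical colour bar is embedded at the right edge.
    """
    s = np.asarray(sigma3, dtype=float)
    if s.shape != (len(spec.footprints),):
        raise ValueError(f"stress vector length {s.shape} does not match ROI size {len(spec.footprints)}")
    wpx, hpx = spec.image_size
    cmap = colormaps[spec.colormap]
    img = np.empty((hpx, wpx, 3), dtype=np.uint8)
    img[:] = spec.background
    t = np.clip((s - spec.vmin) / (spec.vmax - spec.vmin), 0.0, 1.0)
    rgb = (np.asarray(cmap(t))[:, :3] * 255).astype(np.uint8)
    for (r0, r1, c0, c1), col in zip(spec.footprints, rgb):
        img[r0:r1, c0:c1] = col
    # colour bar: vmax at top
    bar_t = np.linspace(1.0, 0.0, hpx)
    bar = (np.asarray(cmap(bar_t))[:, :3] * 255).astype(np.uint8)
    img[:, wpx - spec.colorbar_px :] = bar[:, None, :]
    return Image.fromarray(img)


# ---------------------------------------------------------------------------
# Serving
# ---------------------------------------------------------------------------


def serve(
    rows,
    model: SurrogateModel,
    geometry: PlatformGeometry,
    spec: RenderSpec,
    sink,
    noise_threshold: float = 0.5,
) -> list[float]:
    """Stream rows (t, F1..F4) through resolve -> predict -> render -> sink.

    ``rows`` is an iterable of 5-sequences (or a CSV path with header
    ``t_ms,F1,F2,F3,F4``).  ``sink`` is a directory (frames written as
    numbered PNGs) or a callable(frame_index, image).  Rows below the
    contact threshold render the zero-stress frame; malformed rows are
    skipped with a warning.  Returns per-frame latencies in ms.
    """
    if not model.trained:
        raise ValueError("model is not trained")
    if isinstance(rows, (str, Path)):
        with open(rows) as fh:
            reader = csv.reader(fh)
            parsed = [r for r in reader if r and not r[0].lstrip().startswith(("t", "#"))]
    else:
        parsed = list(rows)
    if callable(sink):
        emit = sink
    else:
        outdir = Path(sink)
        outdir.mkdir(parents=True, exist_ok=True)

        def emit(i, image):
            image.save(outdir / f"frame_{i:05d}.png")

    zero_frame = np.zeros(len(spec.footprints))
    latencies = []
    n_out = 0
    for row in parsed:
        try:
            vals = [float(v) for v in row]
            if len(vals) != 5:
                raise ValueError(f"expected 5 fields, got {len(vals)}")
        except (TypeError, ValueError) as err:
            logger.warning("skipping malformed stream row %r (%s)", row, err)
            continue
        t0 = _time.perf_counter()
        contact = resolve_contact(vals[1:], geometry, noise_threshold=noise_threshold)
        if contact is None:
            s3 = zero_frame
        else:
            x, y, force = contact
            s3 = predict(model, x, y, force)
        image = render_frame(s3, spec)
        latency = 1e3 * (_time.perf_counter() - t0)
        latencies.append(latency)
        emit(n_out, image)
        n_out += 1
    if latencies:
        logger.info(
            "served %d frames, median latency %.2f ms", len(latencies), float(np.median(latencies))
        )
    return latencies


def synthesize_gesture(
    path,
    geometry: PlatformGeometry,
    x: float,
    y: float,
    peak_force: float,
    n_rows: int = 20,
    dt_ms: float = 50.0,
) -> None:
    """Write a scripted press-and-release gesture as a corner-force CSV."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["t_ms", "F1", "F2", "F3", "F4"])
        for i in range(n_rows):
            frac = i / max(n_rows - 1, 1)
            force = peak_force * np.sin(np.pi * frac)
            corners = split_corner_forces(x, y, force, geometry)
            writer.writerow([f"{i * dt_ms:.1f}", *[f"{c:.6f}" for c in corners]])
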