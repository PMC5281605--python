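"""Microstructure metrics on a packed substrate.

A square analysis mask is chosen at the centre of the packing, away from the
ragged periphery of the disk cloud, and the substrate is rasterized inside it
into three tissue labels: extra-axonal (0), myelin (1) and intra-axonal (2).
For each fiber the inner circle (bare axon, diameter d) is drawn inside the
outer circle (myelin periphery, diameter d/g).  From the label areas:

    FVF = (A_intra + A_myelin) / A_tot        fiber volume fraction
    MVF = A_myelin / A_tot                    myelin volume fraction
    AVF = A_intra / A_tot                     axon volume fraction
    fr  = A_intra / (A_intra + A_extra)       restricted water fraction

so that AVF + MVF = FVF and fr = AVF / (1 - MVF) identically.  Residual
disk-disk overlap is quantified analytically (circle-circle lens areas), not
from pixels, so sub-pixel overlaps are detected.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .diameters import AxonPopulation
from .packing import PackingState

__all__ = [
    "AnalysisMask",
    "LabelImage",
    "MicrostructureMetrics",
    "select_mask",
    "rasterize",
    "compute_metrics",
    "fiber_volume_fraction",
    "overlap_ratio",
    "metrics_vs_mask_size",
    "mask_size_error",
    "save_label_png",
]

EXTRA_AXONAL, MYELIN, INTRA_AXONAL = 0, 1, 2

#: default raster resolution, um per pixel (a quarter of the smallest
#: admissible axon diameter, 0.2 um)
DEFAULT_RESOLUTION = 0.05

#: coarser resolution used when tracing FVF along the migration
TRACE_RESOLUTION = 0.1


@dataclass(frozen=True)
class AnalysisMask:
    """Centred square region over which all metrics are computed."""

    center: tuple[float, float]
    side: float

    def __post_init__(self) -> None:
        if self.side <= 0:
            raise ValueError(f"mask side must be positive, got {self.side}")

    @property
    def area(self) -> float:
        return self.side * self.side

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        cx, cy = self.center
        h = self.side / 2.0
        return cx - h, cx + h, cy - h, cy + h


@dataclass
class LabelImage:
    """Three-label raster of the substrate inside a mask."""

    resolution: float
    labels: np.ndarray  # (height, width) uint8 in {0, 1, 2}

    @property
    def width(self) -> int:
        return self.labels.shape[1]

    @property
    def height(self) -> int:
        return self.labels.shape[0]


@dataclass
class MicrostructureMetrics:
    fvf: float
    mvf: float
    avf: float
    fr: float
    r_overlap: float
    n_final: int
    a_intra: float
    a_myelin: float
    a_extra: float
    a_tot: float
    resolution: float

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")


def select_mask(
    state: PackingState,
    population: AxonPopulation,
    margin_factor: float = 2.0,
) -> AnalysisMask:
    """Largest centred square that stays clear of the packing periphery.

    The mask is centred at the centroid of disk centres.  With ``R_cloud``
    the maximum centre distance from the centroid, the half-side is
    ``(R_cloud - margin_factor * max(outer diameter)) / sqrt(2)``: the mask is
    inscribed in a disc that keeps ``margin_factor`` outer diameters of
    clearance from the cloud edge, so no disk intersecting the mask sits on
    the periphery.
    """
    centroid = state.positions.mean(axis=0)
    r_cloud = float(np.sqrt(((state.positions - centroid) ** 2).sum(axis=1)).max())
    margin = margin_factor * float(population.outer_diameters.max())
    half_side = (r_cloud - margin) / np.sqrt(2.0)
    if half_side <= 0:
        raise ValueError(
            "packing cloud too small for an interior analysis mask; "
            "increase the number of axons or reduce margin_factor"
        )
    return AnalysisMask(center=(float(centroid[0]), float(centroid[1])), side=2.0 * half_side)


def count_in_mask(state: PackingState, mask: AnalysisMask) -> int:
    """Number of disks whose centres lie inside the mask (N_final)."""
    x0, x1, y0, y1 = mask.bounds
    x, y = state.positions[:, 0], state.positions[:, 1]
    return int(np.count_nonzero((x >= x0) & (x <= x1) & (y >= y0) & (y <= y1)))


def _paint_circles(grid: np.ndarray, xs, ys, radii, x0, y0, res) -> None:
    """Set True every pixel whose centre lies inside any of the circles."""
    h, w = grid.shape
    for cx, cy, r in zip(xs, ys, radii):
        j0 = max(int(np.floor((cx - r - x0) / res - 0.5)), 0)
        j1 = min(int(np.ceil((cx + r - x0) / res + 0.5)), w)
        i0 = max(int(np.floor((cy - r - y0) / res - 0.5)), 0)
        i1 = min(int(np.ceil((cy + r - y0) / res + 0.5)), h)
        if j0 >= j1 or i0 >= i1:
            continue
        px = x0 + (np.arange(j0, j1) + 0.5) * res
        py = y0 + (np.arange(i0, i1) + 0.5) * res
        inside = (px[None, :] - cx) ** 2 + (py[:, None] - cy) ** 2 <= r * r
        grid[i0:i1, j0:j1] |= inside


def rasterize(
    state: PackingState,
    population: AxonPopulation,
    mask: AnalysisMask,
    resolution: float = DEFAULT_RESOLUTION,
) -> LabelImage:
    """Three-label raster of the substrate restricted to the mask.

    A pixel is intra-axonal if its centre lies inside any inner circle,
    myelin if it lies inside any outer circle but no inner circle, and
    extra-axonal otherwise (union semantics: a pixel claimed by two myelin
    annuli is myelin once).
    """
    if resolution <= 0:
        raise ValueError(f"resolution must be positive, got {resolution}")
    x0, x1, y0, y1 = mask.bounds
    w = max(int(round(mask.side / resolution)), 1)
    x, y = state.positions[:, 0], state.positions[:, 1]
    r_out = population.outer_diameters / 2.0
    r_in = population.inner_diameters / 2.0
    near = (x + r_out >= x0) & (x - r_out <= x1) & (y + r_out >= y0) & (y - r_out <= y1)
    in_outer = np.zeros((w, w), dtype=bool)
    in_inner = np.zeros((w, w), dtype=bool)
    _paint_circles(in_outer, x[near], y[near], r_out[near], x0, y0, resolution)
    _paint_circles(in_inner, x[near], y[near], r_in[near], x0, y0, resolution)
    labels = np.zeros((w, w), dtype=np.uint8)
    labels[in_outer] = MYELIN
    labels[in_inner] = INTRA_AXONAL
    return LabelImage(resolution=resolution, labels=labels)


def compute_metrics(
    image: LabelImage,
    state: PackingState,
    mask: AnalysisMask,
) -> MicrostructureMetrics:
    """Volume fractions from the label image plus the analytic overlap ratio.

    Areas are pixel counts times resolution squared; ``A_tot`` is the pixel
    area of the image so the three label areas partition it exactly.  The
    overlap ratio is computed over disks intersecting the mask.
    """
    px_area = image.resolution**2
    n_px = image.labels.size
    a_intra = float(np.count_nonzero(image.labels == INTRA_AXONAL)) * px_area
    a_myelin = float(np.count_nonzero(image.labels == MYELIN)) * px_area
    a_extra = float(n_px) * px_area - a_intra - a_myelin
    a_tot = float(n_px) * px_area
    fvf = (a_intra + a_myelin) / a_tot
    mvf = a_myelin / a_tot
    avf = a_intra / a_tot
    fr = a_intra / (a_intra + a_extra) if a_intra + a_extra > 0 else 0.0
    x0, x1, y0, y1 = mask.bounds
    x, y = state.positions[:, 0], state.positions[:, 1]
    r = state.packing_diameters / 2.0
    touching = np.nonzero((x + r >= x0) & (x - r <= x1) & (y + r >= y0) & (y - r <= y1))[0]
    return MicrostructureMetrics(
        fvf=fvf,
        mvf=mvf,
        avf=avf,
        fr=fr,
        r_overlap=overlap_ratio(state, touching),
        n_final=count_in_mask(state, mask),
        a_intra=a_intra,
        a_myelin=a_myelin,
        a_extra=a_extra,
        a_tot=a_tot,
        resolution=image.resolution,
    )


def fiber_volume_fraction(
    state: PackingState,
    population: AxonPopulation,
    mask: AnalysisMask | None = None,
    resolution: float = TRACE_RESOLUTION,
) -> float:
    """FVF (packed-fiber area fraction) on the mask, default auto-selected.

    Cheaper than :func:`rasterize` + :func:`compute_metrics` (single boolean
    raster of the outer circles); used to trace density along the migration.
    """
    mask = mask or select_mask(state, population)
    x0, x1, y0, y1 = mask.bounds
    w = max(int(round(mask.side / resolution)), 1)
    x, y = state.positions[:, 0], state.positions[:, 1]
    r_out = population.outer_diameters / 2.0
    near = (x + r_out >= x0) & (x - r_out <= x1) & (y + r_out >= y0) & (y - r_out <= y1)
    in_outer = np.zeros((w, w), dtype=bool)
    _paint_circles(in_outer, x[near], y[near], r_out[near], x0, y0, resolution)
    return float(np.count_nonzero(in_outer)) / in_outer.size


def _lens_area(d: float, r1: float, r2: float) -> float:
    """Intersection area of two circles with radii r1, r2 at centre distance d."""
    if d >= r1 + r2:
        return 0.0
    if d <= abs(r1 - r2):
        r = min(r1, r2)
        return np.pi * r * r
    # standard circular-segment formula
    a1 = r1 * r1 * np.arccos((d * d + r1 * r1 - r2 * r2) / (2.0 * d * r1))
    a2 = r2 * r2 * np.arccos((d * d + r2 * r2 - r1 * r1) / (2.0 * d * r2))
    tri = 0.5 * np.sqrt(
        max((-d + r1 + r2) * (d + r1 - r2) * (d - r1 + r2) * (d + r1 + r2), 0.0)
    )
    return float(a1 + a2 - tri)


def overlap_ratio(state: PackingState, indices: np.ndarray | None = None) -> float:
    """A_overlap / A_disks of the packed disks (gap delta excluded).

    ``A_overlap`` is the sum over pairs of circle-circle lens intersection
    areas; ``A_disks`` the total packed-disk area.  Restricted to ``indices``
    when given.
    """
    if indices is None:
        indices = np.arange(state.n)
    indices = np.asarray(indices)
    if indices.size == 0:
        return 0.0
    pos = state.positions[indices]
    r = state.packing_diameters[indices] / 2.0
    a_disks = float(np.pi * (r**2).sum())
    order = np.argsort(pos[:, 0])
    pos, r = pos[order], r[order]
    a_overlap = 0.0
    r_max = float(r.max())
    # sweep over x: pair (i, j) can only overlap if x_j - x_i < r_i + r_j
    for i in range(len(r) - 1):
        for j in range(i + 1, len(r)):
            dx = pos[j, 0] - pos[i, 0]
            if dx >= r[i] + r_max:
                break
            d = float(np.hypot(dx, pos[j, 1] - pos[i, 1]))
            if d < r[i] + r[j]:
                a_overlap += _lens_area(d, float(r[i]), float(r[j]))
    return a_overlap / a_disks


def metrics_vs_mask_size(
    state: PackingState,
    population: AxonPopulation,
    n_masks: int = 10,
    resolution: float = DEFAULT_RESOLUTION,
    margin_factor: float = 2.0,
) -> pd.DataFrame:
    """Metrics over nested centred masks, smallest to the auto-selected one.

    Returns a DataFrame with columns ``side, n_final, fvf, mvf, avf, fr``,
    one row per mask.  Used to check that the volume fractions are stable
    with respect to the number of disks inside the mask.
    """
    outer = select_mask(state, population, margin_factor=margin_factor)
    sides = np.linspace(outer.side / n_masks, outer.side, n_masks)
    rows = []
    for side in sides:
        mask = AnalysisMask(center=outer.center, side=float(side))
        image = rasterize(state, population, mask, resolution=resolution)
        m = compute_metrics(image, state, mask)
        rows.append(
            {"side": float(side), "n_final": m.n_final, "fvf": m.fvf,
             "mvf": m.mvf, "avf": m.avf, "fr": m.fr}
        )
    return pd.DataFrame(rows)


def mask_size_error(table: pd.DataFrame, stat: str, min_disks: int = 200) -> float:
    """Spread (max - min) of ``stat`` over masks holding more than ``min_disks``."""
    sel = table[table["n_final"] > min_disks]
    if sel.empty:
        raise ValueError(f"no mask holds more than {min_disks} disks; error undefined")
    return float(sel[stat].max() - sel[stat].min())


def save_label_png(image: LabelImage, path: str | Path, colorize: bool = False) -> None:
    """Write the label image as PNG (raw 0/1/2 labels, or a colorized preview)."""
    import imageio.v3 as iio

    if colorize:
        palette = np.array(
            [[180, 180, 180], [0, 0, 0], [255, 255, 255]], dtype=np.uint8
        )  # extra-axonal grey, myelin black, intra-axonal white
        iio.imwrite(Path(path), palette[image.labels])
    else:
        iio.imwrite(Path(path), image.labels)
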