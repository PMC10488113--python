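"""Structural morphometry of segmented cells.

Three families of per-cell measurements:

* **t-system** — transverse-tubule geometry read from the WGA channel.
  The t-system of a cell is recovered as the difference between the
  morphologically closed and the original cell segment, intersected with
  the WGA mask (closing fills intracellular invaginations).  Metrics are
  the mean Euclidean distance of interior pixels to the nearest tubule
  (ΔTT, µm) and the skeleton density (1-px-thinned tubule pixels over
  myocyte pixels).
* **nuclei** — DAPI components assigned to their majority-overlap parent
  cell; area (µm²) and circularity (short/long equivalent-ellipse axis).
* **RyR pattern** — RyR-positive pixel density (%) and spectral
  regularity: the fraction of AC image energy falling in the radial
  spatial-frequency band 1/(2.5 µm) .. 1/(1.5 µm), which brackets the
  sarcomeric z-line period.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy import ndimage as ndi
from skimage.measure import regionprops, label as sk_label
from skimage.morphology import disk, skeletonize

from .image import require_same_grid
from .segmentation import CellLabelMap

#: Spatial-frequency band (µm^-1) bracketing the sarcomere period.
REGULARITY_BAND = (1.0 / 2.5, 1.0 / 1.5)


@dataclass
class TSystemMetrics:
    """ΔTT (µm) and skeleton density of one cell; ``delta_tt_um`` is None
    when the cell has no t-system."""

    cell_id: int
    delta_tt_um: Optional[float]
    skeleton_density: float


@dataclass
class NucleusMetrics:
    nucleus_id: int
    parent_cell_id: int  # 0 when the nucleus overlaps no cell segment
    area_um2: float
    circularity: float   # short axis / long axis, in (0, 1]
    centroid_px: Tuple[float, float]


@dataclass
class RyRPatternMetrics:
    cell_id: int
    density_pct: float
    regularity: Optional[float]
    evaluable: bool  # False when the cell is too small to resolve the band


def extract_t_system(
    labels: CellLabelMap, wga_mask: np.ndarray, closing_radius_px: int = 5
) -> np.ndarray:
    """Label map of t-system pixels (same ids as ``labels``).

    Per cell: closing with a disk of ``closing_radius_px`` fills
    invaginations narrower than twice the radius; the filled-minus-original
    difference restricted to WGA-positive pixels is that cell's t-system.
    Tubule pixels lie outside the cell segment itself (they are
    WGA-positive), so the result is a separate label image.
    """
    lab = labels.labels
    require_same_grid(lab, wga_mask)
    wga = np.asarray(wga_mask, bool)
    out = np.zeros_like(lab)
    if closing_radius_px <= 0:
        warnings.warn("closing radius 0 recovers no t-system", RuntimeWarning,
                      stacklevel=2)
        return out
    footprint = disk(closing_radius_px)
    pad = closing_radius_px + 1
    for sl, k in _iter_cells(lab):
        sl = tuple(
            slice(max(s.start - pad, 0), min(s.stop + pad, n))
            for s, n in zip(sl, lab.shape)
        )
        interior = lab[sl] == k
        # pad with background so the closing cannot latch onto array edges
        padded = np.pad(interior, pad)
        closed = ndi.binary_closing(padded, structure=footprint)
        closed = closed[pad:-pad, pad:-pad]
        t_sys = closed & ~interior & wga[sl]
        # first-written id wins where closings of two cells could touch
        target = out[sl]
        target[t_sys & (target == 0)] = k
    return out


def _iter_cells(lab: np.ndarray):
    for k, sl in enumerate(ndi.find_objects(lab), start=1):
        if sl is not None:
            yield sl, k


def t_system_metrics(
    interior: np.ndarray, t_mask: np.ndarray, pixel_size_um: float,
    cell_id: int = 0,
) -> TSystemMetrics:
    """ΔTT and skeleton density for one cell.

    ΔTT averages, over the cell's interior pixels, the Euclidean distance
    to the nearest t-system pixel.  The skeleton-density denominator is
    the union of interior and t-system pixels ("total myocyte pixels").
    """
    interior = np.asarray(interior, bool)
    t_mask = np.asarray(t_mask, bool)
    require_same_grid(interior, t_mask)
    if not interior.any():
        raise ValueError("cell interior is empty")
    denom = int((interior | t_mask).sum())
    if not t_mask.any():
        return TSystemMetrics(cell_id, None, 0.0)
    dist = ndi.distance_transform_edt(~t_mask, sampling=pixel_size_um)
    delta = float(dist[interior].mean())
    skel = skeletonize(t_mask)
    return TSystemMetrics(cell_id, delta, float(skel.sum() / denom))


def t_system_metrics_all(
    labels: CellLabelMap, t_labels: np.ndarray, pad: int = 8
) -> List[TSystemMetrics]:
    """Per-cell t-system metrics from the label maps, on bounding boxes
    padded enough to keep tubule pixels just outside the interior."""
    lab = labels.labels
    out = []
    for sl, k in _iter_cells(lab):
        sl = tuple(
            slice(max(s.start - pad, 0), min(s.stop + pad, n))
            for s, n in zip(sl, lab.shape)
        )
        m = t_system_metrics(lab[sl] == k, t_labels[sl] == k,
                             labels.pixel_size_um, cell_id=k)
        out.append(m)
    return out


def nucleus_metrics(
    dapi_mask: np.ndarray,
    labels: CellLabelMap,
    pixel_size_um: float,
    min_nucleus_area_um2: float = 10.0,
) -> List[NucleusMetrics]:
    """Detect nuclei as 8-connected DAPI components and measure them.

    Axes come from the component's second central moments
    (equivalent-ellipse axes); circularity is short/long.  The parent
    cell is the segment holding the majority of the nucleus' pixels;
    nuclei overlapping no segment keep parent id 0.
    """
    dapi = np.asarray(dapi_mask, bool)
    lab = labels.labels
    require_same_grid(dapi, lab)
    comp = sk_label(dapi, connectivity=2)
    min_px = min_nucleus_area_um2 / pixel_size_um**2
    out: List[NucleusMetrics] = []
    nucleus_id = 0
    for p in regionprops(comp):
        if p.area < min_px:
            continue
        nucleus_id += 1
        overlapped = lab[comp == p.label]
        vals, cnts = np.unique(overlapped, return_counts=True)
        parent = int(vals[np.argmax(cnts)])
        major = p.axis_major_length
        minor = p.axis_minor_length
        circ = float(minor / major) if major > 0 else 1.0
        out.append(
            NucleusMetrics(
                nucleus_id=nucleus_id,
                parent_cell_id=parent,
                area_um2=float(p.area * pixel_size_um**2),
                circularity=circ,
                centroid_px=tuple(p.centroid),
            )
        )
    return out


def ryr_pattern_metrics(
    ryr_channel: np.ndarray,
    ryr_mask: np.ndarray,
    interior: np.ndarray,
    pixel_size_um: float,
    band: Tuple[float, float] = REGULARITY_BAND,
    cell_id: int = 0,
) -> RyRPatternMetrics:
    """RyR density and spectral regularity of one cell.

    Density is the percentage of RyR-positive (non-dilated) pixels in the
    interior.  Regularity: interior intensities are mean-subtracted and
    zero-padded to the bounding box, the 2D power spectrum is computed,
    and the fraction of total AC power with radial spatial frequency in
    ``band`` is reported.  Cells whose long axis cannot resolve two
    periods of the slowest band frequency (< 2 * 2.5 µm) are flagged not
    evaluable.  Zero AC power yields regularity 0.
    """
    interior = np.asarray(interior, bool)
    ryr_mask = np.asarray(ryr_mask, bool)
    chan = np.asarray(ryr_channel, dtype=np.float64)
    require_same_grid(chan, ryr_mask, interior)
    n_in = int(interior.sum())
    if n_in == 0:
        raise ValueError("cell interior is empty")
    density = 100.0 * int((ryr_mask & interior).sum()) / n_in

    props = regionprops(interior.astype(np.uint8))
    long_axis_um = props[0].axis_major_length * pixel_size_um
    if long_axis_um < 2 * (1.0 / band[0]):
        return RyRPatternMetrics(cell_id, density, None, evaluable=False)

    sl = ndi.find_objects(interior.astype(np.uint8))[0]
    box_in = interior[sl]
    x = chan[sl].copy()
    x -= x[box_in].mean()
    x[~box_in] = 0.0
    power = np.abs(np.fft.fft2(x)) ** 2
    fy = np.fft.fftfreq(x.shape[0], d=pixel_size_um)
    fx = np.fft.fftfreq(x.shape[1], d=pixel_size_um)
    fr = np.hypot(fy[:, None], fx[None, :])
    total = power.sum() - power[0, 0]
    if total <= 0:
        return RyRPatternMetrics(cell_id, density, 0.0, evaluable=True)
    in_band = (fr >= band[0]) & (fr <= band[1])
    in_band[0, 0] = False
    reg = float(power[in_band].sum() / total)
    return RyRPatternMetrics(cell_id, density, reg, evaluable=True)


def ryr_pattern_metrics_all(
    ryr_channel: np.ndarray,
    ryr_mask: np.ndarray,
    labels: CellLabelMap,
    band: Tuple[float, float] = REGULARITY_BAND,
) -> List[RyRPatternMetrics]:
    lab = labels.labels
    out = []
    for sl, k in _iter_cells(lab):
        m = ryr_pattern_metrics(
            ryr_channel[sl], ryr_mask[sl], lab[sl] == k,
            labels.pixel_size_um, band=band, cell_id=k,
        )
        out.append(m)
    return out


def aggregate_by_class(cells_frame, value_columns, class_column="cell_class"):
    """Mean ± standard error of selected per-cell metrics by class."""
    import pandas as pd

    rows = []
    for cls, grp in cells_frame.groupby(class_column):
        row = {"cell_class": cls, "n": len(grp)}
        for col in value_columns:
            vals = grp[col].dropna().to_numpy(dtype=float)
            row[f"{col}_mean"] = vals.mean() if vals.size else np.nan
            row[f"{col}_sem"] = (
                vals.std(ddof=1) / np.sqrt(vals.size) if vals.size > 1 else np.nan
            )
        rows.append(row)
    return pd.DataFrame(rows)
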