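"""Synthetic confocal slice images with per-cell ground truth.

Emulates stained myocardial tissue slices: rod-shaped cardiomyocytes
embedded in WGA-positive extracellular matrix, striated ryanodine-receptor
(RyR) cluster patterns aligned with z-lines in viable cells, homogeneous
cytosolic dextran fill in membrane-permeable (dead) cells, jittered and
blurred RyR clusters in double-positive (dying) cells, elliptical DAPI
nuclei, sparse autofluorescent lipofuscin granules, a smooth background
gradient and Poisson–Gaussian detector noise.

The generator exists so every downstream stage (thresholding,
segmentation, classification, morphometry, diagnostic accuracy) can be
validated against known truth; it renders the qualitative appearance of
the real stains, not their optics (no PSF, no photobleaching, 2D only).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Mapping, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .image import MultiChannelImage, DEFAULT_PIXEL_SIZE_UM

#: Viability states a generated cell can take.  ``double_negative`` cells
#: are myocyte-shaped stand-ins for non-myocytes (e.g. fibroblast patches)
#: carrying neither signal.
STATES = ("live", "dead", "double_positive", "double_negative")

#: Render order is fixed so that a fixed seed yields bit-identical images.
_CHANNEL_ORDER = ("WGA", "RyR", "dextran", "DAPI", "lipofuscin")

_DEFAULT_PROPORTIONS = {
    "live": 0.45,
    "dead": 0.40,
    "double_positive": 0.10,
    "double_negative": 0.05,
}

#: Peak signal amplitudes (12-bit ADU) above the background level.  The
#: source imagery gives no absolute signal-to-background ratios, so these
#: are documented assumptions chosen to give clearly separable histograms.
_DEFAULT_AMPLITUDES = {
    "WGA": 900.0,        # extracellular matrix
    "WGA_tubule": 540.0,  # transverse tubules, dimmer than the ECM sheet
    "RyR": 1500.0,
    "dextran": 800.0,
    "DAPI": 2000.0,
    "lipofuscin": 2500.0,
}

_INTENSITY_MAX = 4095  # 12-bit-like dynamic range


@dataclass(frozen=True)
class SliceSpec:
    """Parameters of one synthetic slice image.

    Lengths are micrometres; (mean, sd) pairs parameterise per-cell
    normal draws.  ``class_proportions`` must sum to 1.
    """

    image_size_px: Tuple[int, int] = (2048, 2048)
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    n_cells_target: int = 20
    cell_length_um: Tuple[float, float] = (60.0, 15.0)
    cell_width_um: Tuple[float, float] = (16.0, 3.0)
    wga_thickness_um: float = 1.0
    sarcomere_period_um: float = 1.9
    class_proportions: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_PROPORTIONS)
    )
    t_system_density_live: float = 0.9
    t_system_density_dead: float = 0.75
    ryr_jitter_um: float = 1.0
    nucleus_area_um2_live: float = 49.4
    nucleus_area_um2_dead: float = 44.0
    nucleus_axis_ratio_live: float = 0.45
    nucleus_axis_ratio_dead: float = 0.60
    lipofuscin_density: float = 0.2  # granules per 100 µm²
    background_gradient_amplitude: float = 0.2
    background_level: float = 60.0
    noise_gain: float = 4.0        # ADU per detected photon
    read_noise_sd: float = 10.0    # additive Gaussian, ADU
    orientation_jitter_deg: float = 6.0
    channel_amplitudes: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_AMPLITUDES)
    )
    seed: int = 0

    def validate(self) -> None:
        h, w = self.image_size_px
        if h <= 0 or w <= 0:
            raise ValueError("image_size_px must be positive")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.n_cells_target < 0:
            raise ValueError("n_cells_target must be >= 0")
        for name in ("cell_length_um", "cell_width_um"):
            mean, sd = getattr(self, name)
            if mean <= 0 or sd < 0:
                raise ValueError(f"{name} requires mean > 0 and sd >= 0")
        for name in (
            "wga_thickness_um",
            "sarcomere_period_um",
            "nucleus_area_um2_live",
            "nucleus_area_um2_dead",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        missing = set(STATES) - set(self.class_proportions)
        if missing:
            raise ValueError(f"class_proportions missing states: {missing}")
        total = sum(self.class_proportions[s] for s in STATES)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class_proportions must sum to 1, got {total}")
        if any(self.class_proportions[s] < 0 for s in STATES):
            raise ValueError("class_proportions must be non-negative")
        for name in ("t_system_density_live", "t_system_density_dead"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.ryr_jitter_um < 0 or self.lipofuscin_density < 0:
            raise ValueError("ryr_jitter_um and lipofuscin_density must be >= 0")
        if self.noise_gain <= 0 or self.read_noise_sd < 0:
            raise ValueError("invalid noise parameters")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["image_size_px"] = list(self.image_size_px)
        d["cell_length_um"] = list(self.cell_length_um)
        d["cell_width_um"] = list(self.cell_width_um)
        d["class_proportions"] = dict(self.class_proportions)
        d["channel_amplitudes"] = dict(self.channel_amplitudes)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SliceSpec":
        d = dict(d)
        for key in ("image_size_px", "cell_length_um", "cell_width_um"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class CellGeometry:
    """Pose of one rod-shaped cell: centre in pixel coordinates (row, col),
    long-axis angle in radians, and rod dimensions in µm."""

    center_px: Tuple[float, float]
    theta: float
    length_um: float
    width_um: float


@dataclass
class GroundTruth:
    """Per-cell truth accompanying a generated slice.

    ``label_map`` assigns 0 to ECM/background and k >= 1 to the interior of
    cell k; ``cell_states[k-1]`` is the state of cell k.
    ``t_line_positions[k-1]`` holds the longitudinal coordinates (µm, cell
    frame, relative to the cell centre) of the z-lines that carry a
    transverse tubule.  ``packing_shortfall`` is set when fewer cells than
    requested could be placed within the bounded packing attempts.
    """

    label_map: np.ndarray
    cell_states: List[str]
    cell_geometry: List[CellGeometry]
    nucleus_params: List[dict]
    t_line_positions: List[np.ndarray]
    packing_shortfall: bool = False

    @property
    def n_cells(self) -> int:
        return len(self.cell_states)

    def states_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"cell_id": np.arange(1, self.n_cells + 1), "state": self.cell_states}
        )


def _cell_frame(bbox, center_px, theta, pixel_size_um, step: int = 1):
    """Longitudinal/transverse µm coordinates for every pixel of a bbox."""
    r0, r1, c0, c1 = bbox
    dy = ((np.arange(r0, r1, step, dtype=np.float32) - center_px[0])
          * pixel_size_um)[:, None]
    dx = ((np.arange(c0, c1, step, dtype=np.float32) - center_px[1])
          * pixel_size_um)[None, :]
    cos_t, sin_t = math.cos(theta), math.sin(theta)
    u = dx * cos_t + dy * sin_t
    v = dy * cos_t - dx * sin_t
    return u, v


def _bbox_for(center_px, theta, length_um, width_um, pixel_size_um, shape, pad_um=0.0):
    half_l = length_um / 2 + pad_um
    half_w = width_um / 2 + pad_um
    ext_x = half_l * abs(math.cos(theta)) + half_w * abs(math.sin(theta))
    ext_y = half_l * abs(math.sin(theta)) + half_w * abs(math.cos(theta))
    er = int(math.ceil(ext_y / pixel_size_um)) + 2
    ec = int(math.ceil(ext_x / pixel_size_um)) + 2
    r0 = max(0, int(center_px[0]) - er)
    r1 = min(shape[0], int(center_px[0]) + er + 1)
    c0 = max(0, int(center_px[1]) - ec)
    c1 = min(shape[1], int(center_px[1]) + ec + 1)
    return (r0, r1, c0, c1)


def _place_cells(spec: SliceSpec, rng: np.random.Generator):
    """Rejection-sampled rod packing with a minimum ECM gap between cells."""
    h, w = spec.image_size_px
    px = spec.pixel_size_um
    gap = spec.wga_thickness_um
    label_map = np.zeros((h, w), dtype=np.int32)
    forbidden = np.zeros((h, w), dtype=bool)
    geometry: List[CellGeometry] = []
    global_dir = rng.uniform(0.0, math.pi)
    jitter = math.radians(spec.orientation_jitter_deg)
    len_mean, len_sd = spec.cell_length_um
    wid_mean, wid_sd = spec.cell_width_um
    max_attempts = 50 * spec.n_cells_target
    attempts = 0
    while len(geometry) < spec.n_cells_target and attempts < max_attempts:
        attempts += 1
        length = float(np.clip(rng.normal(len_mean, len_sd), 0.4 * len_mean, 1.8 * len_mean))
        width = float(np.clip(rng.normal(wid_mean, wid_sd), 0.5 * wid_mean, 1.6 * wid_mean))
        theta = global_dir + rng.normal(0.0, jitter)
        half_l, half_w = length / 2 + gap, width / 2 + gap
        ext_x = half_l * abs(math.cos(theta)) + half_w * abs(math.sin(theta))
        ext_y = half_l * abs(math.sin(theta)) + half_w * abs(math.cos(theta))
        er, ec = ext_y / px + 2, ext_x / px + 2
        if 2 * er >= h or 2 * ec >= w:
            continue  # this rod cannot fit in the image at all
        center = (rng.uniform(er, h - 1 - er), rng.uniform(ec, w - 1 - ec))
        bbox = _bbox_for(center, theta, length, width, px, (h, w), pad_um=gap)
        r0, r1, c0, c1 = bbox
        box_forbidden = forbidden[r0:r1, c0:c1]
        if box_forbidden.any():
            # cheap coarse rejection before the full-resolution test
            cu, cv = _cell_frame(bbox, center, theta, px, step=4)
            coarse = (np.abs(cu) <= half_l) & (np.abs(cv) <= half_w)
            if box_forbidden[::4, ::4][coarse].any():
                continue
        u, v = _cell_frame(bbox, center, theta, px)
        expanded = (np.abs(u) <= half_l) & (np.abs(v) <= half_w)
        if box_forbidden[expanded].any():
            continue
        interior = (np.abs(u) <= length / 2) & (np.abs(v) <= width / 2)
        label_map[r0:r1, c0:c1][interior] = len(geometry) + 1
        forbidden[r0:r1, c0:c1] |= expanded
        geometry.append(CellGeometry(center, float(theta), length, width))
    return label_map, geometry


def generate_slice(spec: SliceSpec) -> Tuple[MultiChannelImage, GroundTruth]:
    """Render one synthetic slice and its ground truth.

    Returns channels ``{WGA, RyR, dextran, DAPI, lipofuscin}`` as uint16
    arrays on a common grid.  Identical ``spec`` (including its ``seed``)
    reproduces bit-identical output.

    Raises
    ------
    ValueError
        If the spec is invalid or the image is too small to place a single
        cell while ``n_cells_target > 0``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_size_px
    px = spec.pixel_size_um
    amps = {**_DEFAULT_AMPLITUDES, **dict(spec.channel_amplitudes)}

    label_map, geometry = _place_cells(spec, rng)
    n_cells = len(geometry)
    if spec.n_cells_target > 0 and n_cells == 0:
        raise ValueError(
            "image too small to place any cell; enlarge image_size_px or "
            "shrink the cell dimensions"
        )
    shortfall = n_cells < spec.n_cells_target
    if shortfall:
        warnings.warn(
            f"placed only {n_cells} of {spec.n_cells_target} requested cells "
            "within the bounded packing attempts",
            RuntimeWarning,
            stacklevel=2,
        )

    probs = np.array([spec.class_proportions[s] for s in STATES], dtype=float)
    state_idx = rng.choice(len(STATES), size=n_cells, p=probs) if n_cells else np.empty(0, int)
    states = [STATES[i] for i in state_idx]

    channels = {
        name: np.full((h, w), spec.background_level, dtype=np.float32)
        for name in _CHANNEL_ORDER
    }
    # ECM: every non-cell pixel carries the WGA sheet signal.
    channels["WGA"][label_map == 0] += amps["WGA"]

    t_density = {
        "live": spec.t_system_density_live,
        "dead": spec.t_system_density_dead,
        "double_positive": spec.t_system_density_dead,
        "double_negative": 0.0,
    }
    nucleus_params: List[dict] = []
    t_line_positions: List[np.ndarray] = []

    for k, geom in enumerate(geometry):
        state = states[k]
        bbox = _bbox_for(geom.center_px, geom.theta, geom.length_um, geom.width_um,
                         px, (h, w))
        r0, r1, c0, c1 = bbox
        u, v = _cell_frame(bbox, geom.center_px, geom.theta, px)
        half_l, half_w = geom.length_um / 2, geom.width_um / 2
        interior = (np.abs(u) <= half_l) & (np.abs(v) <= half_w)

        # z-lines along the long axis with a random phase
        phase = rng.uniform(0.0, spec.sarcomere_period_um)
        z_us = np.arange(-half_l + phase, half_l - 0.3, spec.sarcomere_period_um)

        # transverse tubules on a state-dependent subset of z-lines,
        # rendered as dashed lines in the WGA channel
        carries = rng.random(z_us.size) < t_density[state]
        t_us = z_us[carries]
        t_line_positions.append(t_us.copy())
        if t_us.size:
            wga_box = channels["WGA"][r0:r1, c0:c1]
            dash_phase = rng.uniform(0.0, 1.5, size=t_us.size)
            # nearest tubule per pixel via sorted search
            idx = np.clip(np.searchsorted(t_us, u) - 1, 0, t_us.size - 1)
            right = np.clip(idx + 1, 0, t_us.size - 1)
            d_left = np.abs(u - t_us[idx])
            d_right = np.abs(u - t_us[right])
            use_right = d_right < d_left
            nearest = np.where(use_right, right, idx)
            line = interior & (np.minimum(d_left, d_right) <= 0.15)
            line &= ((v - dash_phase[nearest]) % 1.5) < 1.0  # 1 µm dash, 0.5 µm gap
            np.maximum(wga_box, spec.background_level + amps["WGA_tubule"],
                       out=wga_box, where=line)

        # RyR clusters along z-lines.  Live cells: dense rows (0.3 µm
        # transverse spacing) with tiny positional jitter, merging into
        # quasi-continuous striations after blur, as immunofluorescent
        # z-line staining does.  Double-positive (dying) cells: sparser
        # clusters scrambled by ryr_jitter_um and blurred more strongly —
        # bright but disorganised.
        if state in ("live", "double_positive") and z_us.size:
            n_rows = z_us.size
            v_spacing = 0.3 if state == "live" else 0.8
            v_grid = np.arange(-half_w + 0.4, half_w - 0.3, v_spacing)
            if v_grid.size:
                v_grid = v_grid + rng.uniform(0.0, v_spacing)
                uu = np.repeat(z_us, v_grid.size)
                vv = np.tile(v_grid, n_rows)
                jitter_sd = 0.08 if state == "live" else spec.ryr_jitter_um
                uu = uu + rng.normal(0.0, jitter_sd, uu.size)
                vv = vv + rng.normal(0.0, jitter_sd, vv.size)
                uu = np.clip(uu, -half_l + 0.3, half_l - 0.3)
                vv = np.clip(vv, -half_w + 0.2, half_w - 0.2)
                cos_t, sin_t = math.cos(geom.theta), math.sin(geom.theta)
                rows = geom.center_px[0] + (uu * sin_t + vv * cos_t) / px
                cols = geom.center_px[1] + (uu * cos_t - vv * sin_t) / px
                ri = np.clip(np.rint(rows).astype(int) - r0, 0, r1 - r0 - 1)
                ci = np.clip(np.rint(cols).astype(int) - c0, 0, c1 - c0 - 1)
                sigma_px = (2.0 if state == "live" else 3.0)
                # scale so that a merged striation peaks near amps["RyR"]
                per_cluster = amps["RyR"] * math.sqrt(2 * math.pi) * sigma_px \
                    * (v_spacing / px)
                acc = np.zeros((r1 - r0, c1 - c0), dtype=np.float32)
                np.add.at(acc, (ri, ci), per_cluster)
                acc = gaussian_filter(acc, sigma_px)
                acc[~interior] = 0.0
                channels["RyR"][r0:r1, c0:c1] += acc

        # homogeneous cytosolic dextran fill marks membrane-permeable cells
        if state in ("dead", "double_positive"):
            channels["dextran"][r0:r1, c0:c1][interior] += amps["dextran"]

        # one elliptical nucleus per cell, long axis along the cell
        if state in ("live", "double_negative"):
            area_mean, ratio_mean = spec.nucleus_area_um2_live, spec.nucleus_axis_ratio_live
        else:
            area_mean, ratio_mean = spec.nucleus_area_um2_dead, spec.nucleus_axis_ratio_dead
        area = float(np.clip(rng.normal(area_mean, 0.10 * area_mean),
                             0.5 * area_mean, 1.5 * area_mean))
        ratio = float(np.clip(rng.normal(ratio_mean, 0.05), 0.2, 0.95))
        a_long = math.sqrt(area / (math.pi * ratio))
        b_short = ratio * a_long
        a_long = min(a_long, half_l - 1.0)
        b_short = min(b_short, half_w - 0.5)
        u_off = rng.uniform(-1, 1) * max(0.0, half_l - a_long - 1.0)
        v_off = rng.uniform(-1, 1) * max(0.0, half_w - b_short - 0.5)
        ell = ((u - u_off) / a_long) ** 2 + ((v - v_off) / b_short) ** 2 <= 1.0
        ell &= interior
        channels["DAPI"][r0:r1, c0:c1][ell] += amps["DAPI"]
        cos_t, sin_t = math.cos(geom.theta), math.sin(geom.theta)
        nucleus_params.append(
            {
                "cell_id": k + 1,
                "center_px": (
                    geom.center_px[0] + (u_off * sin_t + v_off * cos_t) / px,
                    geom.center_px[1] + (u_off * cos_t - v_off * sin_t) / px,
                ),
                "long_axis_um": a_long,
                "short_axis_um": b_short,
                "orientation": geom.theta,
            }
        )

    # sparse lipofuscin granules, bleeding into the other channels the way
    # broadband autofluorescence does
    area_um2 = h * w * px * px
    n_granules = rng.poisson(spec.lipofuscin_density * area_um2 / 100.0)
    if n_granules:
        lip = np.zeros((h, w), dtype=np.float32)
        g_rows = rng.uniform(0, h, n_granules)
        g_cols = rng.uniform(0, w, n_granules)
        g_rads = rng.uniform(0.2, 0.5, n_granules) / px
        for gr, gc, grad in zip(g_rows, g_cols, g_rads):
            rr0 = max(0, int(gr - grad) - 1)
            rr1 = min(h, int(gr + grad) + 2)
            cc0 = max(0, int(gc - grad) - 1)
            cc1 = min(w, int(gc + grad) + 2)
            yy, xx = np.mgrid[rr0:rr1, cc0:cc1]
            disk = (yy - gr) ** 2 + (xx - gc) ** 2 <= grad**2
            lip[rr0:rr1, cc0:cc1][disk] = amps["lipofuscin"]
        channels["lipofuscin"] += lip
        channels["RyR"] += 0.6 * lip
        channels["dextran"] += 0.4 * lip
        channels["WGA"] += 0.3 * lip

    # smooth additive background gradient with a random direction
    if spec.background_gradient_amplitude > 0:
        psi = rng.uniform(0.0, 2 * math.pi)
        scale = 2.0 * spec.background_level * spec.background_gradient_amplitude
        rows = (np.arange(h, dtype=np.float32) / max(h - 1, 1) - 0.5)[:, None]
        cols = (np.arange(w, dtype=np.float32) / max(w - 1, 1) - 0.5)[None, :]
        bump = np.float32(scale * math.cos(psi)) * cols \
            + np.float32(scale * math.sin(psi)) * rows
        for name in _CHANNEL_ORDER:
            channels[name] += bump

    # Poisson shot noise on the photon scale, then Gaussian read noise
    out: Dict[str, np.ndarray] = {}
    for name in _CHANNEL_ORDER:
        lam = channels[name]
        np.clip(lam, 0.0, None, out=lam)
        lam /= spec.noise_gain
        noisy = rng.poisson(lam).astype(np.float32)
        noisy *= spec.noise_gain
        if spec.read_noise_sd > 0:
            read = rng.standard_normal(lam.shape, dtype=np.float32)
            read *= spec.read_noise_sd
            noisy += read
        np.rint(noisy, out=noisy)
        np.clip(noisy, 0, _INTENSITY_MAX, out=noisy)
        out[name] = noisy.astype(np.uint16)

    image = MultiChannelImage(out, pixel_size_um=px,
                              metadata={"synthetic": True, "seed": spec.seed})
    truth = GroundTruth(
        label_map=label_map,
        cell_states=states,
        cell_geometry=geometry,
        nucleus_params=nucleus_params,
        t_line_positions=t_line_positions,
        packing_shortfall=shortfall,
    )
    return image, truth


def generate_force_dataset(
    n_slices: int,
    intercept: float = 0.0,
    slope: float = 3500.0,
    noise_sd: float = 400.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic slice-level viability/contraction-force pairs.

    ``living_fraction`` is uniform on [0, 1];
    ``force_uN = intercept + slope * living_fraction + N(0, noise_sd)``.
    Stand-in for biomimetic-chamber force measurements, for exercising the
    regression stage.
    """
    if n_slices < 3:
        raise ValueError("n_slices must be >= 3 to support a regression")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    frac = rng.uniform(0.0, 1.0, n_slices)
    force = intercept + slope * frac + rng.normal(0.0, noise_sd, n_slices)
    return pd.DataFrame({"living_fraction": frac, "force_uN": force})
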