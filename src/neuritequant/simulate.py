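"""Ground-truth-emitting synthetic fluorescence microscopy.

Three generators emulate the assays the quantification pipeline is built
for, each returning rendered channels plus the noise-free object inventory
(the "ground truth") so every downstream stage can be tested without real
image data:

* :func:`simulate_neurite_field` — a corona of neurites crossing a square
  imaging field (0.32 mm² by default), with progressive axotomy-induced
  fragmentation: breakpoints arrive as a Poisson process along each neurite
  at rate ``degeneration / break_spacing_um``, cutting it into fragments
  separated by fixed-width gaps; a fraction of fragments round up into
  near-circular blebs.  Renders a calcein channel and an optional
  colocalizing annexin-V channel.
* :func:`simulate_mitochondria` — elliptical mitochondria placed along the
  neurite skeletons, with aspect ratios drawn from a configurable
  distribution.  Only the polarized fraction appears in the TMRE channel;
  all appear in the cytochrome-c channel.
* :func:`simulate_monolayer_field` — a 2D culture with H-33342 nuclei, a
  viable fraction of calcein-positive somata, and a neurite meshwork.

Noise model: per-object brightness jitter, additive planar illumination
gradient, Poisson photon noise and Gaussian read noise.  Identical
(config, seed) pairs produce bit-identical images and ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dataclass_field
from typing import Literal

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator
from skimage import draw as sk_draw, measure, morphology

from .field import ImageField
from .metrics import classify_ar

__all__ = [
    "NoiseConfig",
    "ArDistribution",
    "SimConfig",
    "GroundTruth",
    "simulate_neurite_field",
    "simulate_mitochondria",
    "simulate_monolayer_field",
]

_STEP_PX = 0.5  # arc-length sampling step for curve rendering


class NoiseConfig(BaseModel):
    """Additive background + photon/read noise parameters (16-bit counts)."""

    model_config = ConfigDict(extra="forbid")

    background_offset: float = Field(default=200.0, ge=0, allow_inf_nan=False)
    background_gradient_amplitude: float = Field(default=80.0, ge=0, allow_inf_nan=False)
    gaussian_sd: float = Field(default=15.0, ge=0, allow_inf_nan=False)
    poisson_scaling: float = Field(default=1.0, ge=0, allow_inf_nan=False)
    """Photon-count scaling for Poisson noise; 0 disables the Poisson stage."""

    @classmethod
    def off(cls) -> "NoiseConfig":
        """Noise-free rendering (used for ground-truth-exact tests)."""
        return cls(
            background_offset=0.0,
            background_gradient_amplitude=0.0,
            gaussian_sd=0.0,
            poisson_scaling=0.0,
        )


class ArDistribution(BaseModel):
    """Named distribution for mitochondrial aspect ratios (clipped at 1)."""

    model_config = ConfigDict(extra="forbid")

    name: Literal["lognormal", "uniform", "fixed", "choice"] = "lognormal"
    mu: float = Field(default=1.0, allow_inf_nan=False)      # lognormal: mean of log AR
    sigma: float = Field(default=0.35, ge=0, allow_inf_nan=False)
    low: float = Field(default=1.1, ge=1.0, allow_inf_nan=False)   # uniform
    high: float = Field(default=5.0, ge=1.0, allow_inf_nan=False)
    value: float = Field(default=2.0, ge=1.0, allow_inf_nan=False)  # fixed
    choices: list[float] | None = None

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if self.name == "lognormal":
            ar = np.exp(rng.normal(self.mu, self.sigma, size))
        elif self.name == "uniform":
            ar = rng.uniform(self.low, self.high, size)
        elif self.name == "fixed":
            ar = np.full(size, self.value)
        else:
            if not self.choices:
                raise ValueError("choice distribution requires non-empty 'choices'")
            ar = rng.choice(np.asarray(self.choices, dtype=float), size)
        return np.maximum(ar, 1.0)


class SimConfig(BaseModel):
    """Full simulator configuration.

    Defaults describe the 10× imaging geometry (0.32 mm² square field) used
    for the degeneration time courses; mitochondrial morphometry was done at
    63×, so mito-oriented runs typically override ``pixel_size_um`` (~0.1)
    and ``field_area_um2`` accordingly.
    """

    model_config = ConfigDict(extra="forbid")

    # --- geometry / rendering ---
    field_area_um2: float = Field(default=320_000.0, gt=0, allow_inf_nan=False)
    pixel_size_um: float = Field(default=0.65, gt=0, allow_inf_nan=False)
    bit_depth: Literal[8, 16] = 16
    signal_amplitude: float = Field(default=8000.0, gt=0, allow_inf_nan=False)
    noise: NoiseConfig = Field(default_factory=NoiseConfig)
    seed: int = 0

    # --- 2.5D neurite corona ---
    n_neurites: int = Field(default=30, ge=0)
    neurite_width_um: float = Field(default=1.5, gt=0, allow_inf_nan=False)
    degeneration: float = Field(default=0.0, ge=0, le=1, allow_inf_nan=False)
    bleb_fraction: float = Field(default=0.5, ge=0, le=1, allow_inf_nan=False)
    break_spacing_um: float = Field(default=20.0, gt=0, allow_inf_nan=False)
    gap_um: float = Field(default=2.0, gt=0, allow_inf_nan=False)
    layout: Literal["radial", "bands"] = "radial"
    annexin_positive_fraction: float = Field(default=0.0, ge=0, le=1, allow_inf_nan=False)

    # --- mitochondria ---
    mito_density_per_100um: float = Field(default=12.0, ge=0, allow_inf_nan=False)
    mito_min_spacing_um: float = Field(default=2.0, ge=0, allow_inf_nan=False)
    """Hard-core exclusion along the skeleton: mitochondria are solid
    organelles, so sampled positions closer than this arc distance to an
    already-placed one are thinned out."""
    mito_minor_um: float = Field(default=1.0, gt=0, allow_inf_nan=False)
    mito_ar_distribution: ArDistribution = Field(default_factory=ArDistribution)
    polarized_fraction: float = Field(default=1.0, ge=0, le=1, allow_inf_nan=False)

    # --- 2D monolayer ---
    n_nuclei: int = Field(default=200, ge=0)
    viable_fraction: float = Field(default=1.0, ge=0, le=1, allow_inf_nan=False)
    nucleus_radius_um: float = Field(default=5.0, gt=0, allow_inf_nan=False)
    soma_extra_um: float = Field(default=3.5, ge=0, allow_inf_nan=False)
    soma_expand_um: float = Field(default=3.2, ge=0, allow_inf_nan=False)
    neurites_per_cell: int = Field(default=3, ge=0)
    cell_neurite_length_um: float = Field(default=60.0, ge=0, allow_inf_nan=False)
    cell_neurite_width_um: float = Field(default=1.0, gt=0, allow_inf_nan=False)
    deterministic_viability: bool = False

    @model_validator(mode="after")
    def _intensities_fit_bit_depth(self) -> "SimConfig":
        peak = (
            self.signal_amplitude
            + self.noise.background_offset
            + self.noise.background_gradient_amplitude
        )
        if peak > (1 << self.bit_depth) - 1:
            raise ValueError(
                f"signal_amplitude + background exceeds the {self.bit_depth}-bit "
                f"range ({peak} > {(1 << self.bit_depth) - 1})"
            )
        return self

    @property
    def field_px(self) -> int:
        """Square field side in pixels: round(sqrt(field_area)/pixel_size)."""
        return round(math.sqrt(self.field_area_um2) / self.pixel_size_um)


@dataclass
class GroundTruth:
    """Noise-free object inventory emitted alongside generated images."""

    true_object_count: int
    true_mean_fragment_area_um2: float
    true_neurite_area_um2: float
    object_areas_um2: np.ndarray
    non_touching: bool
    true_coloc_fraction: float | None = None
    mito_records: pd.DataFrame | None = None
    # 2D monolayer extras
    n_nuclei: int | None = None
    n_viable: int | None = None
    true_soma_area_um2: float | None = None
    true_neurite_area_outside_soma_um2: float | None = None
    # plumbing: fragment center-line paths in px, reused for mito placement
    skeletons: list = dataclass_field(default_factory=list)
    # plumbing: flat pixel indices per rendered object (noise-free mask)
    object_pixels: list = dataclass_field(default_factory=list)

    def summary_row(self) -> dict:
        """Flat scalar summary, suitable for one CSV row per field."""
        return {
            "true_object_count": self.true_object_count,
            "true_mean_fragment_area_um2": self.true_mean_fragment_area_um2,
            "true_neurite_area_um2": self.true_neurite_area_um2,
            "non_touching": self.non_touching,
            "true_coloc_fraction": self.true_coloc_fraction,
            "n_nuclei": self.n_nuclei,
            "n_viable": self.n_viable,
            "true_soma_area_um2": self.true_soma_area_um2,
            "true_neurite_area_outside_soma_um2": self.true_neurite_area_outside_soma_um2,
        }


# ---------------------------------------------------------------------------
# geometry helpers


def _disk_offsets(radius_px: float) -> np.ndarray:
    r = max(int(np.ceil(radius_px)), 0)
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    inside = yy**2 + xx**2 <= radius_px**2 + 1e-9
    return np.argwhere(inside) - r


def _pixels_for_points(shape: tuple[int, int], pts: np.ndarray, radius_px: float) -> np.ndarray:
    """Unique flat indices of the union of disks stamped at each point."""
    h, w = shape
    centers = np.unique(np.round(np.atleast_2d(pts)).astype(np.int64), axis=0)
    offs = _disk_offsets(radius_px)
    pix = (centers[:, None, :] + offs[None, :, :]).reshape(-1, 2)
    ok = (pix[:, 0] >= 0) & (pix[:, 0] < h) & (pix[:, 1] >= 0) & (pix[:, 1] < w)
    pix = pix[ok]
    return np.unique(pix[:, 0] * w + pix[:, 1])


def _wander_path(
    rng: np.random.Generator,
    start: tuple[float, float],
    heading: float,
    n_px: int,
    wander_sd: float,
    max_len_px: float,
    y_bounds: tuple[float, float] | None = None,
    mean_revert: float = 0.97,
    max_turn: float = 0.5,
) -> np.ndarray:
    """Smooth, locally directional random curve ((y, x) rows).

    The heading follows a mean-reverting (Ornstein–Uhlenbeck) walk around
    the base direction, clamped to ``±max_turn`` — so curves meander but
    never double back on themselves, which keeps fragments of one neurite
    spatially separated by their arc-length gaps.  Truncated at the field
    border.
    """
    from scipy.signal import lfilter

    n_steps = max(int(max_len_px / _STEP_PX), 1)
    noise = rng.normal(0.0, wander_sd, n_steps)
    deviation = lfilter([1.0], [1.0, -mean_revert], noise)
    headings = heading + np.clip(deviation, -max_turn, max_turn)
    ys = start[0] + np.concatenate(([0.0], np.cumsum(_STEP_PX * np.sin(headings))))
    xs = start[1] + np.concatenate(([0.0], np.cumsum(_STEP_PX * np.cos(headings))))
    if y_bounds is not None:
        ys = np.clip(ys, y_bounds[0], y_bounds[1])
    inside = (ys >= 0) & (ys <= n_px - 1) & (xs >= 0) & (xs <= n_px - 1)
    if inside.all():
        end = len(ys)
    else:
        end = int(np.argmin(inside))
    return np.column_stack([ys[: max(end, 2)], xs[: max(end, 2)]])


def _neurite_paths(rng: np.random.Generator, cfg: SimConfig) -> list[np.ndarray]:
    n = cfg.field_px
    w_px = cfg.neurite_width_um / cfg.pixel_size_um
    paths = []
    if cfg.layout == "bands":
        band_h = n / max(cfg.n_neurites, 1)
        # margin covers the widest stamp (a capped bleb) so adjacent bands
        # can never touch; this is what makes bands-layout fields certifiable
        margin = 1.5 * w_px + 2
        for i in range(cfg.n_neurites):
            y0 = i * band_h
            yc = y0 + band_h / 2
            lo, hi = y0 + margin, min(y0 + band_h - margin, n - 1)
            paths.append(
                _wander_path(
                    rng, (yc, 0.0), 0.0, n, wander_sd=0.05,
                    max_len_px=1.1 * n, y_bounds=(lo, max(hi, lo)),
                    mean_revert=0.95, max_turn=0.3,
                )
            )
    else:  # radial corona: enter from a random edge, head inward
        for _ in range(cfg.n_neurites):
            side = rng.integers(4)
            t = rng.uniform(0, n - 1)
            if side == 0:
                start, base = (0.0, t), math.pi / 2
            elif side == 1:
                start, base = (float(n - 1), t), -math.pi / 2
            elif side == 2:
                start, base = (t, 0.0), 0.0
            else:
                start, base = (t, float(n - 1)), math.pi
            heading = base + rng.uniform(-0.6, 0.6)
            paths.append(
                _wander_path(
                    rng, start, heading, n, wander_sd=0.08, max_len_px=2.2 * n,
                    mean_revert=0.97, max_turn=0.6,
                )
            )
    return paths


def _fragment_intervals(
    rng: np.random.Generator, length_um: float, cfg: SimConfig
) -> tuple[list[tuple[float, float]], bool]:
    """Arc-length intervals (µm) surviving Poisson breakage; True if broken.

    Fragment ends are trimmed by half the neurite width at each cut so the
    rendered masks of neighboring fragments sit ``gap_um`` apart edge to
    edge.
    """
    lam = cfg.degeneration * length_um / cfg.break_spacing_um
    n_breaks = int(rng.poisson(lam)) if lam > 0 else 0
    if n_breaks == 0:
        return [(0.0, length_um)], False
    centers = np.sort(rng.uniform(0.0, length_um, n_breaks))
    # trim by half the width so masks sit gap_um apart edge to edge, plus one
    # pixel against rounding of stamp centers to the grid
    half = cfg.gap_um / 2 + cfg.neurite_width_um / 2 + cfg.pixel_size_um
    min_len = max(cfg.pixel_size_um, 0.25 * cfg.neurite_width_um)
    intervals: list[tuple[float, float]] = []
    prev = 0.0
    for c in centers:
        a, b = prev, c - half
        if b - a >= min_len:
            intervals.append((a, b))
        prev = c + half
    if length_um - prev >= min_len:
        intervals.append((prev, length_um))
    return intervals, True


# ---------------------------------------------------------------------------
# rendering


def _render_channel(
    amplitude: np.ndarray, cfg: SimConfig, rng: np.random.Generator
) -> np.ndarray:
    """Background + gradient + Poisson + Gaussian noise, quantized to uints."""
    img = amplitude.astype(np.float64) + cfg.noise.background_offset
    if cfg.noise.background_gradient_amplitude > 0:
        theta = rng.uniform(0, 2 * math.pi)
        n0, n1 = img.shape
        yy = np.linspace(0, 1, n0)[:, None]
        xx = np.linspace(0, 1, n1)[None, :]
        u = math.cos(theta) * xx + math.sin(theta) * yy
        u = (u - u.min()) / max(u.max() - u.min(), 1e-12)
        img = img + cfg.noise.background_gradient_amplitude * u
    if cfg.noise.poisson_scaling > 0:
        s = cfg.noise.poisson_scaling
        img = rng.poisson(img * s).astype(np.float64) / s
    if cfg.noise.gaussian_sd > 0:
        img = img + rng.normal(0.0, cfg.noise.gaussian_sd, img.shape)
    max_value = (1 << cfg.bit_depth) - 1
    img = np.clip(np.rint(img), 0, max_value)
    return img.astype(np.uint8 if cfg.bit_depth == 8 else np.uint16)


def _make_field(
    pixels: np.ndarray, cfg: SimConfig, channel: str, ids: dict[str, str]
) -> ImageField:
    return ImageField(
        pixels=pixels,
        pixel_size=cfg.pixel_size_um,
        bit_depth=cfg.bit_depth,
        channel=channel,
        **ids,
    )


# ---------------------------------------------------------------------------
# generators


def simulate_neurite_field(
    config: SimConfig,
    field_id: str = "",
    well_id: str = "",
    condition_id: str = "",
) -> tuple[dict[str, ImageField], GroundTruth]:
    """Render one neurite-corona field (calcein + annexin channels).

    Returns the channel dictionary and the :class:`GroundTruth` inventory;
    ``ground_truth.skeletons`` holds the surviving fragment center lines for
    :func:`simulate_mitochondria`.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = cfg.field_px
    ps = cfg.pixel_size_um
    w_px = cfg.neurite_width_um / ps
    ids = {"field_id": field_id, "well_id": well_id, "condition_id": condition_id}

    amp = np.zeros((n, n), dtype=np.float64)
    object_pixels: list[np.ndarray] = []
    skeletons: list[np.ndarray] = []

    for path in _neurite_paths(rng, cfg):
        length_um = (len(path) - 1) * _STEP_PX * ps
        intervals, broken = _fragment_intervals(rng, length_um, cfg)
        for a_um, b_um in intervals:
            i0 = int(np.ceil(a_um / (_STEP_PX * ps)))
            i1 = int(np.floor(b_um / (_STEP_PX * ps)))
            if i1 <= i0:
                continue
            seg = path[i0 : i1 + 1]
            frag_len_um = (len(seg) - 1) * _STEP_PX * ps
            as_bleb = broken and rng.random() < cfg.bleb_fraction
            if as_bleb:
                # area-preserving radius, capped so blebs stay bead-sized
                r_um = min(
                    max(
                        math.sqrt(frag_len_um * cfg.neurite_width_um / math.pi),
                        cfg.neurite_width_um / 2,
                    ),
                    1.5 * cfg.neurite_width_um,
                )
                center = seg[len(seg) // 2]
                flat = _pixels_for_points((n, n), center[None, :], r_um / ps)
            else:
                flat = _pixels_for_points((n, n), seg, w_px / 2)
                skeletons.append(seg)
            if flat.size == 0:
                continue
            object_pixels.append(flat)
            amp.ravel()[flat] = cfg.signal_amplitude * rng.uniform(0.85, 1.15)

    n_objects = len(object_pixels)
    mask = amp > 0
    labels = measure.label(mask, connectivity=2)
    non_touching = int(labels.max()) == n_objects

    areas_um2 = np.array([f.size for f in object_pixels], dtype=float) * ps**2
    neurite_area_um2 = float(np.count_nonzero(mask)) * ps**2

    # annexin-V channel: a fraction of calcein+ objects expose the signal
    annexin_amp = np.zeros_like(amp)
    coloc_fraction: float | None = None
    annexin_flags = rng.random(n_objects) < cfg.annexin_positive_fraction
    annexin_jitter = rng.uniform(0.85, 1.15, n_objects)
    for flat, pos, jit in zip(object_pixels, annexin_flags, annexin_jitter):
        if pos:
            annexin_amp.ravel()[flat] = cfg.signal_amplitude * jit
    if mask.any():
        coloc_fraction = float(np.count_nonzero(annexin_amp > 0)) / float(
            np.count_nonzero(mask)
        )

    channels = {
        "calcein": _make_field(_render_channel(amp, cfg, rng), cfg, "calcein", ids),
        "annexin": _make_field(_render_channel(annexin_amp, cfg, rng), cfg, "annexin", ids),
    }
    gt = GroundTruth(
        true_object_count=n_objects,
        true_mean_fragment_area_um2=float(areas_um2.mean()) if n_objects else float("nan"),
        true_neurite_area_um2=neurite_area_um2,
        object_areas_um2=areas_um2,
        non_touching=non_touching,
        true_coloc_fraction=coloc_fraction,
        skeletons=skeletons,
        object_pixels=object_pixels,
    )
    return channels, gt


def simulate_mitochondria(
    config: SimConfig,
    skeletons: list[np.ndarray],
    field_id: str = "",
    well_id: str = "",
    condition_id: str = "",
) -> tuple[dict[str, ImageField], pd.DataFrame]:
    """Place elliptical mitochondria along neurite skeletons.

    Counts per skeleton are Poisson with mean ``mito_density_per_100um``
    per 100 µm of arc length.  Every mitochondrion appears in the
    cytochrome-c channel; only the polarized fraction takes up TMRE.
    Returns the two channels and a record table with one row per
    mitochondrion (true center, axes, aspect ratio, shape class per the
    AR<1.5 / AR>3 rule, polarized flag).
    """
    cfg = config
    rng = np.random.default_rng([cfg.seed, 104729])
    n = cfg.field_px
    ps = cfg.pixel_size_um
    ids = {"field_id": field_id, "well_id": well_id, "condition_id": condition_id}

    tmre_amp = np.zeros((n, n), dtype=np.float64)
    cytc_amp = np.zeros((n, n), dtype=np.float64)
    records: list[dict] = []
    mito_id = 0

    for pts in skeletons:
        length_um = (len(pts) - 1) * _STEP_PX * ps
        lam = cfg.mito_density_per_100um * length_um / 100.0
        count = int(rng.poisson(lam)) if lam > 0 else 0
        if count == 0:
            continue
        positions = np.sort(rng.uniform(0, len(pts) - 1, count))
        if cfg.mito_min_spacing_um > 0 and count > 1:
            min_idx_gap = cfg.mito_min_spacing_um / (_STEP_PX * ps)
            kept = [positions[0]]
            for p in positions[1:]:
                if p - kept[-1] >= min_idx_gap:
                    kept.append(p)
            positions = np.asarray(kept)
            count = len(positions)
        ars = cfg.mito_ar_distribution.sample(rng, count)
        minors = cfg.mito_minor_um * rng.uniform(0.85, 1.15, count)
        jitter = rng.normal(0.0, cfg.neurite_width_um / 4 / ps, (count, 2))
        polarized = rng.random(count) < cfg.polarized_fraction
        amps = cfg.signal_amplitude * rng.uniform(0.85, 1.15, count)
        for k in range(count):
            i = int(positions[k])
            tangent = pts[min(i + 1, len(pts) - 1)] - pts[max(i - 1, 0)]
            angle = math.atan2(tangent[0], tangent[1])
            cy, cx = pts[i] + jitter[k]
            major_um = ars[k] * minors[k]
            rr, cc = sk_draw.ellipse(
                cy,
                cx,
                max(minors[k] / 2 / ps, 0.5),
                max(major_um / 2 / ps, 0.5),
                shape=(n, n),
                rotation=angle,
            )
            if rr.size == 0:
                yy, xx = int(round(cy)), int(round(cx))
                if not (0 <= yy < n and 0 <= xx < n):
                    continue
                rr = np.array([yy])
                cc = np.array([xx])
            mito_id += 1
            cytc_amp[rr, cc] = amps[k]
            if polarized[k]:
                tmre_amp[rr, cc] = amps[k]
            records.append(
                {
                    "mito_id": mito_id,
                    "center_x": float(cx),
                    "center_y": float(cy),
                    "major_um": float(major_um),
                    "minor_um": float(minors[k]),
                    "aspect_ratio": float(ars[k]),
                    "shape_class": str(classify_ar(ars[k])[()]),
                    "polarized": bool(polarized[k]),
                }
            )

    channels = {
        "tmre": _make_field(_render_channel(tmre_amp, cfg, rng), cfg, "tmre", ids),
        "cytc": _make_field(_render_channel(cytc_amp, cfg, rng), cfg, "cytc", ids),
    }
    columns = [
        "mito_id", "center_x", "center_y", "major_um", "minor_um",
        "aspect_ratio", "shape_class", "polarized",
    ]
    table = pd.DataFrame(records, columns=columns)
    return channels, table


def simulate_monolayer_field(
    config: SimConfig,
    field_id: str = "",
    well_id: str = "",
    condition_id: str = "",
) -> tuple[dict[str, ImageField], GroundTruth]:
    """Render a 2D monolayer field (H-33342 nuclei + calcein channels).

    Every cell gets a nuclear disk; the viable fraction additionally gets a
    calcein-positive soma (nucleus radius + ``soma_extra_um``) with a small
    neurite meshwork.  Ground truth records the viable count and the
    noise-free calcein area outside the somata (nuclei expanded by
    ``soma_expand_um``), mirroring the downstream scoring.
    """
    cfg = config
    rng = np.random.default_rng([cfg.seed, 1299709])
    n = cfg.field_px
    ps = cfg.pixel_size_um
    ids = {"field_id": field_id, "well_id": well_id, "condition_id": condition_id}

    r_nuc_px = cfg.nucleus_radius_um / ps
    r_soma_px = (cfg.nucleus_radius_um + cfg.soma_extra_um) / ps
    min_sep_px = 2 * r_soma_px + 3
    margin = r_soma_px + 1

    centers: list[np.ndarray] = []
    attempts = 0
    max_attempts = 400 * max(cfg.n_nuclei, 1) + 1000
    while len(centers) < cfg.n_nuclei:
        attempts += 1
        if attempts > max_attempts:
            raise ValueError(
                f"could not place {cfg.n_nuclei} non-overlapping cells in a "
                f"{n}x{n} px field; reduce n_nuclei or the soma radius"
            )
        cand = rng.uniform(margin, n - 1 - margin, 2)
        if all(np.hypot(*(cand - c)) >= min_sep_px for c in centers):
            centers.append(cand)

    n_cells = len(centers)
    if cfg.deterministic_viability:
        n_viable_target = round(cfg.viable_fraction * n_cells)
        order = rng.permutation(n_cells)
        viable = np.zeros(n_cells, dtype=bool)
        viable[order[:n_viable_target]] = True
    else:
        viable = rng.random(n_cells) < cfg.viable_fraction

    nuc_amp = np.zeros((n, n), dtype=np.float64)
    cal_amp = np.zeros((n, n), dtype=np.float64)
    w_neur_px = cfg.cell_neurite_width_um / ps

    for idx, c in enumerate(centers):
        nuc_flat = _pixels_for_points((n, n), c[None, :], r_nuc_px)
        nuc_amp.ravel()[nuc_flat] = cfg.signal_amplitude * rng.uniform(0.85, 1.15)
        if not viable[idx]:
            continue
        soma_flat = _pixels_for_points((n, n), c[None, :], r_soma_px)
        cal_amp.ravel()[soma_flat] = cfg.signal_amplitude * rng.uniform(0.85, 1.15)
        for _ in range(cfg.neurites_per_cell):
            angle = rng.uniform(0, 2 * math.pi)
            start = (
                c[0] + r_soma_px * math.sin(angle),
                c[1] + r_soma_px * math.cos(angle),
            )
            length_px = cfg.cell_neurite_length_um / ps * rng.uniform(0.6, 1.4)
            path = _wander_path(rng, start, angle, n, wander_sd=0.1, max_len_px=length_px)
            flat = _pixels_for_points((n, n), path, w_neur_px / 2)
            cal_amp.ravel()[flat] = cfg.signal_amplitude * rng.uniform(0.7, 1.0)

    nuclei_mask = nuc_amp > 0
    calcein_mask = cal_amp > 0
    expand_px = round(cfg.soma_expand_um / ps)
    soma_mask = morphology.dilation(nuclei_mask, morphology.disk(expand_px))
    neurite_outside_px = int(np.count_nonzero(calcein_mask & ~soma_mask))

    channels = {
        "calcein": _make_field(_render_channel(cal_amp, cfg, rng), cfg, "calcein", ids),
        "hoechst": _make_field(_render_channel(nuc_amp, cfg, rng), cfg, "hoechst", ids),
    }
    gt = GroundTruth(
        true_object_count=n_cells,
        true_mean_fragment_area_um2=float("nan"),
        true_neurite_area_um2=float(np.count_nonzero(calcein_mask)) * ps**2,
        object_areas_um2=np.array([]),
        non_touching=True,
        n_nuclei=n_cells,
        n_viable=int(viable.sum()),
        true_soma_area_um2=float(np.count_nonzero(soma_mask)) * ps**2,
        true_neurite_area_outside_soma_um2=neurite_outside_px * ps**2,
    )
    return channels, gt
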