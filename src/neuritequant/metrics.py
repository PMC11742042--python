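"""Derived readouts: degeneration indices, mitochondrial morphometry,
thresholded Manders colocalization, background-corrected integrated
intensity, and 2D viability / neurite-area scoring.

Conventions
-----------
* Neurite integrity is the mean segmented-object area of a field expressed
  as percent of an intact (uncut or freshly isolated) control; the
  fragmentation index is the object count as percent of a completely
  degenerated control.  Anchors are computed per biological replicate.
* Mitochondrial shape classes from the fitted-ellipse aspect ratio:
  AR < 1.5 round, AR > 3 elongated, boundary values intermediate (strict
  inequalities on both sides).
* Manders M1/M2 use per-channel thresholds (Otsu by default): M1 is the
  above-threshold intensity of channel A residing in pixels where B is also
  above its threshold, divided by all above-threshold A intensity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage import segmentation as sk_segmentation

from .field import ImageField
from .segment import binarize, label_components, measure_particles, otsu_threshold, watershed_split

__all__ = [
    "Anchor",
    "DegenerationScores",
    "MitoStats",
    "ColocResult",
    "MonolayerScores",
    "anchor_from_particles",
    "degeneration_scores",
    "mito_density",
    "classify_ar",
    "classify_shapes",
    "manders",
    "integrated_intensity",
    "monolayer_scores",
]

ROUND_AR_MAX = 1.5
ELONGATED_AR_MIN = 3.0


@dataclass(frozen=True)
class Anchor:
    """Normalization anchor derived from a designated control field/condition."""

    mean_area_um2: float
    count: float
    condition_id: str = ""


@dataclass(frozen=True)
class DegenerationScores:
    integrity_pct: float
    fragmentation_pct: float
    raw_mean_object_area_um2: float
    raw_object_count: int
    intact_anchor: Anchor
    degenerated_anchor: Anchor


@dataclass(frozen=True)
class MitoStats:
    """Shape-class fractions with the sampling-validity flag.

    ``valid`` requires more than 100 evaluated mitochondria from at least 5
    independent fields, the sampling rule used for morphometry.
    """

    fraction_round: float
    fraction_intermediate: float
    fraction_elongated: float
    n_evaluated: int
    n_fields: int

    @property
    def valid(self) -> bool:
        return self.n_evaluated > 100 and self.n_fields >= 5


@dataclass(frozen=True)
class ColocResult:
    m1: float
    m2: float
    threshold_a: float
    threshold_b: float
    n_pixels_evaluated: int


@dataclass(frozen=True)
class MonolayerScores:
    raw_viability: float
    n_viable: int
    n_nuclei: int
    neurite_area_um2: float
    calcein_threshold: float
    nuclei_threshold: float


def anchor_from_particles(particles: pd.DataFrame, condition_id: str = "") -> Anchor:
    """Build a normalization anchor from a control field's particle table."""
    if len(particles) == 0:
        raise ValueError(
            f"control condition {condition_id!r} produced zero objects; "
            "cannot anchor normalization"
        )
    return Anchor(
        mean_area_um2=float(particles["area_um2"].mean()),
        count=float(len(particles)),
        condition_id=condition_id,
    )


def degeneration_scores(
    field_particles: pd.DataFrame,
    intact_anchor: Anchor,
    degenerated_anchor: Anchor,
) -> DegenerationScores:
    """Integrity and fragmentation indices for one field.

    integrity = 100 · mean(object areas) / intact mean area;
    fragmentation = 100 · object count / degenerated count.
    """
    for anchor, role in ((intact_anchor, "intact"), (degenerated_anchor, "degenerated")):
        if anchor.count <= 0 or anchor.mean_area_um2 <= 0:
            raise ValueError(
                f"{role} control anchor ({anchor.condition_id!r}) has zero objects"
            )
    n = len(field_particles)
    mean_area = float(field_particles["area_um2"].mean()) if n else 0.0
    return DegenerationScores(
        integrity_pct=100.0 * mean_area / intact_anchor.mean_area_um2,
        fragmentation_pct=100.0 * n / degenerated_anchor.count,
        raw_mean_object_area_um2=mean_area,
        raw_object_count=n,
        intact_anchor=intact_anchor,
        degenerated_anchor=degenerated_anchor,
    )


def mito_density(
    tmre_particles: pd.DataFrame,
    neurite_mask: np.ndarray,
    pixel_size: float,
) -> float:
    """Mitochondria per µm² of neurite-covered area.

    The denominator is the calcein-positive (neurite) mask area; an empty
    mask signals a failed field and raises rather than dividing by zero.
    """
    npx = int(np.count_nonzero(neurite_mask))
    if npx == 0:
        raise ValueError("empty neurite mask: no area to normalize to (failed field)")
    return len(tmre_particles) / (npx * pixel_size**2)


def classify_ar(ar) -> np.ndarray:
    """Shape class for aspect-ratio value(s): 'round' | 'intermediate' | 'elongated'."""
    ar = np.asarray(ar, dtype=np.float64)
    out = np.full(ar.shape, "intermediate", dtype=object)
    out[ar < ROUND_AR_MAX] = "round"
    out[ar > ELONGATED_AR_MIN] = "elongated"
    return out


def classify_shapes(particles: pd.DataFrame, n_fields: int = 1) -> MitoStats:
    """Round/intermediate/elongated fractions over a particle table.

    Boundary aspect ratios (exactly 1.5 or 3.0) fall in "intermediate".
    Fractions sum to 1 for any nonempty table; an empty table yields NaN
    fractions and an invalid result.
    """
    n = len(particles)
    if n == 0:
        return MitoStats(np.nan, np.nan, np.nan, 0, n_fields)
    classes = classify_ar(particles["aspect_ratio"].to_numpy())
    n_round = int(np.sum(classes == "round"))
    n_elong = int(np.sum(classes == "elongated"))
    return MitoStats(
        fraction_round=n_round / n,
        fraction_intermediate=(n - n_round - n_elong) / n,
        fraction_elongated=n_elong / n,
        n_evaluated=n,
        n_fields=n_fields,
    )


def manders(
    img_a: ImageField,
    img_b: ImageField,
    thresholds: tuple[float, float] | None = None,
) -> ColocResult:
    """Thresholded Manders colocalization coefficients (1 = total, 0 = none).

    With per-channel thresholds (tA, tB), M1 is the summed A intensity over
    pixels above threshold in both channels divided by the summed A
    intensity over all A-positive pixels; M2 is symmetric.  Thresholds
    default to per-channel Otsu.
    """
    a = np.asarray(img_a.pixels, dtype=np.float64)
    b = np.asarray(img_b.pixels, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"channel shapes differ: {a.shape} vs {b.shape}")
    if thresholds is None:
        thresholds = (otsu_threshold(img_a), otsu_threshold(img_b))
    t_a, t_b = thresholds
    pos_a = a > t_a
    pos_b = b > t_b
    denom_a = float(a[pos_a].sum())
    denom_b = float(b[pos_b].sum())
    if denom_a == 0:
        raise ValueError(f"no positive pixels in channel {img_a.channel or 'A'!r}")
    if denom_b == 0:
        raise ValueError(f"no positive pixels in channel {img_b.channel or 'B'!r}")
    both = pos_a & pos_b
    return ColocResult(
        m1=float(a[both].sum()) / denom_a,
        m2=float(b[both].sum()) / denom_b,
        threshold_a=float(t_a),
        threshold_b=float(t_b),
        n_pixels_evaluated=int(pos_a.sum() + pos_b.sum() - both.sum()),
    )


def integrated_intensity(
    img: ImageField,
    object_mask: np.ndarray,
    background_region: np.ndarray,
) -> float:
    """Background-corrected integrated intensity over a mask.

    Sum of intensities over ``object_mask`` minus the mean of a single
    unspecific-background region times the mask size, floored at 0 — the
    densitometric quantification also used for annexin-V signal.
    """
    object_mask = np.asarray(object_mask, dtype=bool)
    background_region = np.asarray(background_region, dtype=bool)
    if not background_region.any():
        raise ValueError("background region is empty")
    if (object_mask & background_region).any():
        raise ValueError("background region overlaps the object mask")
    pixels = np.asarray(img.pixels, dtype=np.float64)
    total = float(pixels[object_mask].sum())
    bg_mean = float(pixels[background_region].mean())
    return max(total - bg_mean * int(object_mask.sum()), 0.0)


def _foreground_mask(img: ImageField) -> np.ndarray:
    """Otsu foreground; a constant channel has no foreground."""
    try:
        return binarize(img, otsu_threshold(img))
    except ValueError:
        return np.zeros(img.shape, dtype=bool)


def monolayer_scores(
    calcein: ImageField,
    nuclei: ImageField,
    expand_um: float = 3.2,
    viable_soma_fraction: float = 0.3,
    min_nucleus_area_um2: float = 20.0,
    thresholds: tuple[float, float] | None = None,
) -> MonolayerScores:
    """Viability and neurite area for a 2D monolayer field.

    Nuclei are segmented (Otsu + watershed) from the H-33342 channel; cell
    somata are the nuclei expanded by ``expand_um`` (3.2 µm by default).  A
    cell counts as calcein/H-33342 double-positive (viable) when at least
    ``viable_soma_fraction`` of its soma-region pixels exceed the calcein
    threshold — the per-cell rule is a package choice, exposed as a
    parameter.  Neurite area is the calcein-positive area outside all
    somata, in µm².  Values are raw per-field; normalization to untreated
    controls happens at aggregation.
    """
    if expand_um < 0:
        raise ValueError(f"expand_um must be >= 0, got {expand_um}")
    ps = nuclei.pixel_size
    if thresholds is not None:
        t_calcein, t_nuclei = thresholds
        nuclei_mask = binarize(nuclei, t_nuclei)
        calcein_mask = binarize(calcein, t_calcein)
    else:
        t_nuclei = np.nan
        t_calcein = np.nan
        nuclei_mask = _foreground_mask(nuclei)
        calcein_mask = _foreground_mask(calcein)
        if nuclei_mask.any():
            t_nuclei = otsu_threshold(nuclei)
        if calcein_mask.any():
            t_calcein = otsu_threshold(calcein)
    labels = watershed_split(nuclei_mask)
    nucleus_table = measure_particles(labels, nuclei, min_area_um2=min_nucleus_area_um2)
    n_nuclei = len(nucleus_table)
    if n_nuclei == 0:
        raise ValueError("zero nuclei detected in the H-33342 channel")
    keep = np.isin(labels, nucleus_table["label"].to_numpy())
    labels = np.where(keep, labels, 0)

    expand_px = round(expand_um / ps)
    soma_labels = sk_segmentation.expand_labels(labels, distance=expand_px)
    soma_union = soma_labels > 0

    n_labels = int(soma_labels.max()) + 1
    soma_px = np.bincount(soma_labels.ravel(), minlength=n_labels)
    calcein_px = np.bincount(
        soma_labels[calcein_mask].ravel(), minlength=n_labels
    )
    label_ids = nucleus_table["label"].to_numpy()
    with np.errstate(invalid="ignore"):
        frac = calcein_px[label_ids] / soma_px[label_ids]
    n_viable = int(np.sum(frac >= viable_soma_fraction))

    neurite_px = int(np.count_nonzero(calcein_mask & ~soma_union))
    return MonolayerScores(
        raw_viability=n_viable / n_nuclei,
        n_viable=n_viable,
        n_nuclei=n_nuclei,
        neurite_area_um2=neurite_px * ps**2,
        calcein_threshold=float(t_calcein),
        nuclei_threshold=float(t_nuclei),
    )
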