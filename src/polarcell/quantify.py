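"""Measurement procedures: shape descriptors, orientation, recoil velocity.

These mirror the image-analysis pipeline used on wing epithelial cells —
circularity and Feret axes of a traced cell outline, structure-tensor
orientation of filament textures with 3-category angular binning,
junction-intensity normalization, and post-ablation recoil velocity —
applied here to simulated phase fields and synthetic images.

Conventions: orientations are axial (defined modulo 180°) and folded to
(−90°, 90°], with 0° the proximal–distal (x) axis.  Images are indexed
``image[row, col]`` with row = y and col = x in a Cartesian frame
(display with ``origin='lower'``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import shapely.geometry as sgeom
from skimage import measure
from skimage.feature import structure_tensor

from .fields import OrientationField, PhaseField, indicator

__all__ = [
    "ShapeMetrics",
    "CellContour",
    "OrientationHistogram",
    "OrientationMap",
    "AblationTrack",
    "circularity",
    "fold_axial_angle",
    "extract_contour",
    "shape_metrics",
    "feret_diameters",
    "orientation_histogram_from_field",
    "orientation_from_image",
    "bin_angles",
    "recoil_velocity",
    "normalize_junction_intensity",
]

SIGNED3_LABELS = ("-30..30", "+-30..60", "+-60..90")
ABSOLUTE3_LABELS = ("0..30", "30..60", "60..90")


def circularity(area: float, perimeter: float) -> float:
    """Circularity = 4π·Area/perimeter²; 1 for a perfect circle."""
    if perimeter <= 0:
        raise ValueError("perimeter must be positive")
    return 4.0 * np.pi * area / perimeter**2


def fold_axial_angle(angle_deg):
    """Fold an axial angle (mod 180°) into (−90°, 90°]."""
    a = np.asarray(angle_deg, dtype=float)
    folded = ((a + 90.0) % 180.0) - 90.0
    folded = np.where(np.isclose(folded, -90.0), 90.0, folded)
    return folded if folded.ndim else float(folded)


# ---------------------------------------------------------------------------
# contours and shape descriptors
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CellContour:
    """Zero-level-set outline of a cell: the largest closed component."""

    polygon: np.ndarray  # (n, 2) closed polygon vertices in physical (x, y)
    multiplicity: int  # number of closed components found


class NoContourError(ValueError):
    """The phase field has no zero crossing."""


def extract_contour(phase: PhaseField) -> CellContour:
    """Extract the φ = 0 polygon by marching squares (linear interpolation).

    If several closed components exist the largest by area is returned
    and the multiplicity records the component count.
    """
    phi = phase.values
    if phi.min() >= 0.0 or phi.max() <= 0.0:
        raise NoContourError("phase field has no sign change: no φ=0 contour")
    contours = measure.find_contours(phi, 0.0)
    h = phase.grid.h
    closed = []
    for c in contours:
        if len(c) >= 4 and np.allclose(c[0], c[-1]):
            closed.append(c * h)  # rows are (i, j) -> (x, y) since x = i·h
    if not closed:
        raise NoContourError("no closed φ=0 contour found (interface touches boundary?)")
    areas = [abs(_shoelace(c)) for c in closed]
    best = int(np.argmax(areas))
    return CellContour(polygon=closed[best], multiplicity=len(closed))


def _shoelace(poly: np.ndarray) -> float:
    x, y = poly[:, 0], poly[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


@dataclass(frozen=True)
class ShapeMetrics:
    """Shape descriptors of one cell outline.

    ``circularity`` is stored exactly as 4π·area/perimeter²; the
    elongation index is the Feret major/minor ratio;
    ``major_axis_angle`` is the axial direction (degrees, in (−90, 90],
    0 = P/D axis) of the maximizing caliper.
    """

    area: float
    perimeter: float
    circularity: float
    feret_major: float
    feret_minor: float
    elongation_index: float
    major_axis_angle: float

    def as_dict(self) -> dict:
        return {
            "area": self.area,
            "perimeter": self.perimeter,
            "circularity": self.circularity,
            "feret_major": self.feret_major,
            "feret_minor": self.feret_minor,
            "elongation_index": self.elongation_index,
            "major_axis_angle": self.major_axis_angle,
        }


def feret_diameters(polygon: np.ndarray) -> tuple[float, float, float]:
    """(max caliper, min caliper, major-axis angle in degrees).

    The maximum Feret diameter is the largest pairwise distance between
    convex-hull vertices; the minimum caliper width is the smallest
    hull width over all hull-edge directions (rotating calipers).
    """
    hull = sgeom.Polygon(polygon).convex_hull
    pts = np.asarray(hull.exterior.coords)[:-1]
    # max caliper: largest pairwise distance
    diff = pts[:, None, :] - pts[None, :, :]
    d2 = np.einsum("ijk,ijk->ij", diff, diff)
    i, j = np.unravel_index(np.argmax(d2), d2.shape)
    feret_major = float(np.sqrt(d2[i, j]))
    v = pts[j] - pts[i]
    angle = fold_axial_angle(np.degrees(np.arctan2(v[1], v[0])))
    # min caliper: smallest width over edge normals
    edges = np.roll(pts, -1, axis=0) - pts
    lengths = np.hypot(edges[:, 0], edges[:, 1])
    keep = lengths > 0
    normals = np.stack([-edges[keep, 1], edges[keep, 0]], axis=1) / lengths[keep, None]
    proj = normals @ pts.T
    widths = proj.max(axis=1) - proj.min(axis=1)
    feret_minor = float(widths.min())
    return feret_major, feret_minor, float(angle)


def shape_metrics(polygon: np.ndarray) -> ShapeMetrics:
    """Shape descriptors of a simple closed polygon (≥ 3 vertices)."""
    poly = np.asarray(polygon, dtype=float)
    if len(poly) >= 2 and np.allclose(poly[0], poly[-1]):
        poly = poly[:-1]
    if len(poly) < 3:
        raise ValueError("polygon needs at least 3 distinct vertices")
    shp = sgeom.Polygon(poly)
    if not shp.is_valid:
        shp = shp.buffer(0)
    area = float(shp.area)
    if area <= 0:
        raise ValueError("degenerate polygon with zero area")
    perimeter = float(shp.length)
    fmaj, fmin, angle = feret_diameters(poly)
    return ShapeMetrics(
        area=area,
        perimeter=perimeter,
        circularity=circularity(area, perimeter),
        feret_major=fmaj,
        feret_minor=fmin,
        elongation_index=fmaj / fmin,
        major_axis_angle=angle,
    )


# ---------------------------------------------------------------------------
# orientation analysis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OrientationHistogram:
    """Weighted 3-category angular histogram.

    ``signed3`` partitions (−90, 90] into [−30, 30) (along P/D),
    ±[30, 60) and ±[60, 90]; ``absolute3`` is the same partition stated
    on absolute angles [0, 90].  Bins are left-closed/right-open with
    the last bin closed at 90.
    """

    scheme: str
    labels: tuple[str, ...]
    counts: np.ndarray
    total_weight: float

    @property
    def fractions(self) -> np.ndarray:
        if self.total_weight <= 0:
            return np.zeros_like(self.counts)
        return self.counts / self.total_weight


def bin_angles(angles, weights=None, scheme: str = "signed3") -> OrientationHistogram:
    """Bin axial angles (degrees) into the three angular categories.

    Angles are folded to (−90, 90] first; both schemes reduce to the
    absolute angle |θ| with edges 0/30/60/90 (left-closed, last closed),
    which is exactly the ± pairing of the signed scheme.
    """
    a = np.atleast_1d(np.asarray(angles, dtype=float))
    if a.size == 0:
        raise ValueError("empty angle list")
    if scheme not in ("signed3", "absolute3"):
        raise ValueError(f"unknown scheme {scheme!r}; use 'signed3' or 'absolute3'")
    w = np.ones_like(a) if weights is None else np.atleast_1d(np.asarray(weights, float))
    if w.shape != a.shape:
        raise ValueError("weights must match angles")
    abs_a = np.abs(fold_axial_angle(a))
    idx = np.digitize(abs_a, [30.0, 60.0])  # [0,30) -> 0, [30,60) -> 1, [60,90] -> 2
    counts = np.zeros(3)
    for k in range(3):
        counts[k] = w[idx == k].sum()
    labels = SIGNED3_LABELS if scheme == "signed3" else ABSOLUTE3_LABELS
    return OrientationHistogram(
        scheme=scheme, labels=labels, counts=counts, total_weight=float(w.sum())
    )


def orientation_histogram_from_field(
    orient: OrientationField, mask: np.ndarray, scheme: str = "signed3"
) -> OrientationHistogram:
    """Angular histogram of the orientation field over the cell interior.

    Per-node axis angles atan2(py, px) folded to (−90, 90], weighted by
    |P|; ``mask`` (e.g. φ̃ > 0.5) selects the interior nodes.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty interior mask")
    px = orient.px[mask]
    py = orient.py[mask]
    angles = fold_axial_angle(np.degrees(np.arctan2(py, px)))
    weights = np.hypot(px, py)
    return bin_angles(angles, weights=weights, scheme=scheme)


def interior_mask(phase: PhaseField, threshold: float = 0.5) -> np.ndarray:
    """Boolean cell-interior mask φ̃ > threshold."""
    return indicator(phase) > threshold


@dataclass(frozen=True)
class OrientationMap:
    """Per-pixel structure-tensor orientation of an image."""

    angle: np.ndarray  # degrees in (−90, 90], valid only where ``valid``
    coherence: np.ndarray  # (λ1−λ2)/(λ1+λ2) in [0, 1]
    valid: np.ndarray  # coherence above threshold

    def coherent_angles(self) -> np.ndarray:
        return self.angle[self.valid]


def orientation_from_image(
    image: np.ndarray,
    window_sigma: float = 2.0,
    coherence_threshold: float = 0.2,
) -> OrientationMap:
    """Local orientation and coherence from the Gaussian structure tensor.

    The structure tensor J is the σ-windowed outer product of intensity
    gradients; the feature orientation (direction of least intensity
    variation, e.g. along a filament) is perpendicular to the dominant
    gradient direction: θ = ½·atan2(2J_xy, J_xx − J_yy) + 90°, folded to
    (−90°, 90°].  Coherence (λ1−λ2)/(λ1+λ2) gauges anisotropy; pixels
    below the threshold are flagged invalid.  A constant image yields
    zero coherent pixels, not an error.
    """
    if window_sigma <= 0:
        raise ValueError("window_sigma must be positive")
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a single-channel 2D image")
    Arr, Arc, Acc = structure_tensor(img, sigma=window_sigma, mode="nearest", order="rc")
    # rows are y, cols are x: J_yy = Arr, J_xy = Arc, J_xx = Acc
    jxx, jxy, jyy = Acc, Arc, Arr
    grad_angle = 0.5 * np.degrees(np.arctan2(2.0 * jxy, jxx - jyy))
    angle = np.asarray(fold_axial_angle(grad_angle + 90.0))
    trace = jxx + jyy
    lam_diff = np.sqrt((jxx - jyy) ** 2 + 4.0 * jxy**2)
    with np.errstate(divide="ignore", invalid="ignore"):
        coherence = np.where(trace > 0, lam_diff / np.where(trace > 0, trace, 1.0), 0.0)
    return OrientationMap(
        angle=angle, coherence=coherence, valid=coherence > coherence_threshold
    )


# ---------------------------------------------------------------------------
# ablation tracks and junction intensities
# ---------------------------------------------------------------------------

ABLATION_DT = 0.2  # s between tracked frames
ABLATION_SPAN = 2.0  # s of post-ablation tracking


@dataclass(frozen=True)
class AblationTrack:
    """Vertex-separation distances after a junction ablation.

    Distances (µm) between the two tracked vertices, sampled every
    200 ms from t = 0 over 2 s.
    """

    times: np.ndarray  # s
    distances: np.ndarray  # µm

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        d = np.asarray(self.distances, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "distances", d)
        if t.shape != d.shape or t.ndim != 1 or t.size < 2:
            raise ValueError("times and distances must be matching 1D arrays (n ≥ 2)")
        if abs(t[0]) > 1e-9:
            raise ValueError("track must start at t = 0")
        if not np.allclose(np.diff(t), ABLATION_DT, atol=1e-9):
            raise ValueError("track must be sampled every 200 ms")
        if np.any(d < 0):
            raise ValueError("distances must be non-negative")


def recoil_velocity(track: AblationTrack) -> float:
    """Initial recoil velocity (µm/s): displacement over the first 200 ms.

    v = (d(0.2 s) − d(0)) / 0.2 s, the linear-range estimate used as a
    proxy for junctional tension.
    """
    if track.times.size < 2:
        raise ValueError("need samples at t = 0 and t = 0.2 s")
    return float((track.distances[1] - track.distances[0]) / ABLATION_DT)


def normalize_junction_intensity(junction_means, background, control_means):
    """Background-subtract and normalize junction intensities.

    Each junction mean has the background subtracted and is then divided
    by the mean background-subtracted intensity of the control junctions
    (posterior-side junctions in the original assay).
    """
    j = np.atleast_1d(np.asarray(junction_means, dtype=float))
    c = np.atleast_1d(np.asarray(control_means, dtype=float))
    if c.size < 1:
        raise ValueError("need at least one control junction")
    if background < 0:
        raise ValueError("background must be non-negative")
    denom = float(np.mean(c - background))
    if denom <= 0:
        raise ValueError("control mean after background subtraction must be positive")
    return (j - background) / denom
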