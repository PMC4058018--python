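"""Semi-automated CMC counting from multichannel fluorescence slides.

The algorithm mirrors the original semi-automated workflow: the DAPI channel
is thresholded with the iterative intermeans (isodata) rule and binarized
into nuclear masks; candidate nuclei are filtered on area, aspect ratio,
circularity and margin sharpness; per-cell red (CD45) and green (melanoma
marker) intensities are measured over a cytoplasmic annulus; global red and
green thresholds are chosen from the per-cell intensity distributions (with
a stringency bias against green for patient slides and toward green for
healthy controls); and every nucleated object is assigned to one of four
classes — green (putative CMC), red (leukocyte), yellow (dual positive) or
null.  Dual positives and anuclear debris are tallied but never counted as
CMCs; objects touching a FOV border are excluded to avoid double counting
across the acquisition grid.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import measure, morphology, segmentation

from .enumeration import SlideCount
from .io import FOVImage, SlideImageSet


class DegenerateHistogramError(ValueError):
    """Histogram has fewer than two occupied bins; no threshold exists."""


class ThresholdError(ValueError):
    """Raised when global thresholds cannot be derived from the cells."""


@dataclass(frozen=True)
class ThresholdPair:
    """Global per-cell intensity thresholds for the red and green channels."""

    t_red: float
    t_green: float
    mode: str = "explicit"

    def __post_init__(self):
        for name in ("t_red", "t_green"):
            v = getattr(self, name)
            if not 0 <= v <= 255:
                raise ValueError(f"{name} must be in [0, 255], got {v}")


@dataclass(frozen=True)
class NucleusObject:
    """One segmented nucleus with its shape metrics."""

    label: int
    area: float
    perimeter: float
    centroid: tuple[float, float]
    aspect_ratio: float
    circularity: float
    margin_score: float
    bbox: tuple[int, int, int, int]
    fov_index: int = 0


@dataclass
class CellObject:
    """A measured cell: nucleus plus channel intensities and class label."""

    nucleus: NucleusObject | None
    green_mean: float
    red_mean: float
    green_nuclear_mean: float
    green_cv: float
    border: bool = False
    pattern_observed: str = ""
    class_label: str | None = None


@dataclass(frozen=True)
class CountConfig:
    """All cut-offs of the counting algorithm, in image units.

    Shape filters follow the nuclear-mask step (area in px^2, aspect ratio
    major/minor, circularity 4*pi*A/P^2, margin score = mean boundary
    gradient / mean interior intensity).  ``stringency`` multiplies the
    green threshold in patient mode and divides it in control mode.
    ``t_red``/``t_green`` force explicit thresholds when both are set.
    """

    min_area: float = 30.0
    max_area: float = 5000.0
    ar_max: float = 2.5
    circ_min: float = 0.6
    margin_min: float = 0.15
    annulus_width: int = 4
    stringency: float = 1.25
    green_cv_punctate: float = 0.6
    threshold_mode: str = "patient"
    t_red: float | None = None
    t_green: float | None = None
    marker: str = "MelanA"
    noise_floor_sigma: float = 6.0
    min_debris_area: float = 20.0

    def __post_init__(self):
        if not 0 < self.min_area <= self.max_area:
            raise ValueError("need 0 < min_area <= max_area")
        if self.ar_max < 1:
            raise ValueError("ar_max must be >= 1")
        if not 0 < self.circ_min <= 1:
            raise ValueError("circ_min must be in (0, 1]")
        if self.threshold_mode not in ("patient", "control", "explicit"):
            raise ValueError(f"unknown threshold_mode {self.threshold_mode!r}")
        if self.marker not in ("MelanA", "S100B"):
            raise ValueError(f"marker must be MelanA or S100B, got {self.marker!r}")

    def replace(self, **kw) -> "CountConfig":
        return dataclasses.replace(self, **kw)


# ---------------------------------------------------------------------------
# Thresholding


def isodata_threshold(histogram) -> int:
    """Iterative intermeans (isodata) threshold of a 256-bin histogram.

    Starting from the midpoint of the occupied intensity range, iterate
    ``t <- round((mean_below(t) + mean_above(t)) / 2)`` (below = bins <= t)
    to its fixed point.  This is the classic automatic threshold on the
    0-255 scale.
    """
    hist = np.asarray(histogram, dtype=float)
    if hist.shape != (256,):
        raise ValueError(f"expected a 256-bin histogram, got shape {hist.shape}")
    occupied = np.nonzero(hist > 0)[0]
    if occupied.size < 2:
        raise DegenerateHistogramError(
            "histogram has fewer than two occupied bins; no threshold exists"
        )
    bins = np.arange(256, dtype=float)
    wx = hist * bins
    csum_w = np.cumsum(hist)
    csum_wx = np.cumsum(wx)
    total_w, total_wx = csum_w[-1], csum_wx[-1]

    def next_t(t):
        mb = csum_wx[t] / csum_w[t]
        ma = (total_wx - csum_wx[t]) / (total_w - csum_w[t])
        return int(np.floor((mb + ma) / 2.0 + 0.5))

    t = int((occupied[0] + occupied[-1]) // 2)
    t = min(max(t, occupied[0]), occupied[-1] - 1)
    seen = set()
    while t not in seen:
        seen.add(t)
        tn = next_t(t)
        tn = min(max(tn, occupied[0]), occupied[-1] - 1)
        if tn == t:
            return t
        t = tn
    return t  # bounded oscillation: return current iterate


def _robust_noise_floor(channel: np.ndarray, k: float) -> float:
    """Median + k * MAD-sigma of a channel; a floor no nucleus may fall under."""
    med = float(np.median(channel))
    mad = float(np.median(np.abs(channel.astype(float) - med)))
    return med + k * 1.4826 * mad


# ---------------------------------------------------------------------------
# Shape metrics and nuclear masks


def shape_metrics(binary) -> tuple[float, float, float, float]:
    """(area, perimeter, aspect_ratio, circularity) of one binary object.

    Circularity is 4*pi*area/perimeter^2 clamped to <= 1; aspect ratio is
    the major/minor axis ratio of the best-fit ellipse (>= 1).
    """
    binary = np.asarray(binary).astype(bool)
    if not binary.any():
        raise ValueError("empty object")
    props = measure.regionprops(binary.astype(np.uint8))[0]
    area = float(props.area)
    perimeter = float(props.perimeter)
    minor = props.axis_minor_length
    aspect = float(props.axis_major_length / minor) if minor > 0 else float("inf")
    circ = 1.0 if perimeter == 0 else min(1.0, 4.0 * np.pi * area / perimeter**2)
    return area, perimeter, max(1.0, aspect), circ


def _margin_score(dapi_grad, obj_mask, interior_mean) -> float:
    boundary = segmentation.find_boundaries(obj_mask, mode="inner")
    if not boundary.any() or interior_mean <= 0:
        return 0.0
    return float(dapi_grad[boundary].mean() / interior_mean)


def nuclear_mask(
    dapi: np.ndarray, config: CountConfig, fov_index: int = 0
) -> tuple[list[NucleusObject], np.ndarray]:
    """Segment and shape-filter nuclei in a DAPI channel.

    Thresholds with :func:`isodata_threshold` (floored at a robust noise
    level so a nucleus-free FOV yields nothing), labels 8-connected
    components, and drops objects failing the area, aspect-ratio,
    circularity or margin-sharpness filters.  Returns the accepted nuclei
    and the full binary foreground mask (used to exclude nuclear pixels
    from cytoplasmic measurements).
    """
    dapi = np.asarray(dapi)
    hist = np.bincount(dapi.ravel(), minlength=256)[:256]
    try:
        t = isodata_threshold(hist)
    except DegenerateHistogramError:
        return [], np.zeros(dapi.shape, dtype=bool)
    t = max(float(t), _robust_noise_floor(dapi, config.noise_floor_sigma))
    mask = dapi > t
    labels = measure.label(mask, connectivity=2)
    grad = None
    nuclei = []
    dapi_f = dapi.astype(float)
    for props in measure.regionprops(labels, intensity_image=dapi_f):
        if not (config.min_area <= props.area <= config.max_area):
            continue
        minor = props.axis_minor_length
        aspect = props.axis_major_length / minor if minor > 0 else float("inf")
        if aspect > config.ar_max:
            continue
        perim = props.perimeter
        circ = 1.0 if perim == 0 else min(1.0, 4.0 * np.pi * props.area / perim**2)
        if circ < config.circ_min:
            continue
        if grad is None:
            grad = ndimage.gaussian_gradient_magnitude(dapi_f, sigma=1.0)
        r0, c0, r1, c1 = props.bbox
        win = (slice(max(r0 - 2, 0), min(r1 + 2, dapi.shape[0])),
               slice(max(c0 - 2, 0), min(c1 + 2, dapi.shape[1])))
        obj = labels[win] == props.label
        score = _margin_score(grad[win], obj, props.intensity_mean)
        if score < config.margin_min:
            continue
        nuclei.append(
            NucleusObject(
                label=props.label,
                area=float(props.area),
                perimeter=float(perim),
                centroid=tuple(map(float, props.centroid)),
                aspect_ratio=float(max(1.0, aspect)),
                circularity=float(circ),
                margin_score=score,
                bbox=tuple(props.bbox),
                fov_index=fov_index,
            )
        )
    return nuclei, mask


# ---------------------------------------------------------------------------
# Per-cell measurement


def measure_cell(
    fov: FOVImage,
    nucleus: NucleusObject,
    nuclei_mask: np.ndarray,
    labels: np.ndarray | None = None,
    annulus_width: int = 4,
) -> CellObject:
    """Measure one cell's channel intensities over a cytoplasmic annulus.

    The annulus is the nucleus dilated by ``annulus_width`` px minus all
    nuclear foreground pixels.  ``green_cv`` is the per-pixel coefficient of
    variation of green in the annulus (0 when the mean is 0); cells whose
    annulus would leave the image are flagged as border objects and excluded
    from tallies downstream.
    """
    shape = fov.shape
    r0, c0, r1, c1 = nucleus.bbox
    pad = annulus_width + 2
    border = r0 - pad < 0 or c0 - pad < 0 or r1 + pad > shape[0] or c1 + pad > shape[1]
    win = (slice(max(r0 - pad, 0), min(r1 + pad, shape[0])),
           slice(max(c0 - pad, 0), min(c1 + pad, shape[1])))
    if labels is not None:
        obj = labels[win] == nucleus.label
    else:
        obj = nuclei_mask[win]
    ring = morphology.dilation(obj, morphology.disk(annulus_width))
    annulus = ring & ~nuclei_mask[win]

    green = fov.channels["marker"][win].astype(float)
    red = fov.channels["cd45"][win].astype(float)
    if annulus.any():
        g = green[annulus]
        green_mean = float(g.mean())
        red_mean = float(red[annulus].mean())
        green_cv = float(g.std() / green_mean) if green_mean > 0 else 0.0
    else:
        green_mean = red_mean = green_cv = 0.0
    green_nuclear = float(green[obj].mean()) if obj.any() else 0.0
    return CellObject(
        nucleus=nucleus,
        green_mean=green_mean,
        red_mean=red_mean,
        green_nuclear_mean=green_nuclear,
        green_cv=green_cv,
        border=border,
    )


# ---------------------------------------------------------------------------
# Global thresholds and classification


def _isodata_on_values(values) -> float:
    hist = np.bincount(np.clip(np.rint(values).astype(int), 0, 255), minlength=256)
    try:
        return float(isodata_threshold(hist))
    except DegenerateHistogramError:
        # all cells share one intensity bin: threshold at that value
        return float(np.rint(values).astype(int)[0])


def select_thresholds(
    cells: list[CellObject],
    mode: str = "patient",
    stringency: float = 1.25,
    explicit: tuple[float, float] | None = None,
) -> ThresholdPair:
    """Choose global red/green thresholds from per-cell mean intensities.

    The default is the intermeans threshold of each per-cell intensity
    distribution.  Patient mode biases against the green signal (threshold
    multiplied by ``stringency`` > 1); control mode biases toward green
    (divided by ``stringency``), reflecting the greater stringency applied
    to patient slides whose sandwich-assay background runs higher.
    ``explicit`` values pass through unchanged.
    """
    if mode == "explicit":
        if explicit is None:
            raise ThresholdError("explicit mode requires (t_red, t_green) values")
        t_red, t_green = explicit
        return ThresholdPair(t_red=t_red, t_green=t_green, mode="explicit")
    if stringency <= 0:
        raise ValueError("stringency must be > 0")
    if len(cells) < 10:
        raise ThresholdError(
            f"only {len(cells)} measured cells; too few to derive global "
            "thresholds — pass explicit (t_red, t_green) instead"
        )
    greens = np.array([c.green_mean for c in cells])
    reds = np.array([c.red_mean for c in cells])
    t_green = _isodata_on_values(greens)
    t_red = _isodata_on_values(reds)
    if mode == "patient":
        t_green = min(255.0, t_green * stringency)
    elif mode == "control":
        t_green = t_green / stringency
    else:
        raise ValueError(f"unknown threshold mode {mode!r}")
    return ThresholdPair(t_red=t_red, t_green=t_green, mode=mode)


def classify_object(
    cell: CellObject,
    thresholds: ThresholdPair,
    marker: str = "MelanA",
    margin_min: float = 0.15,
    green_cv_punctate: float = 0.6,
) -> str:
    """Assign one measured object to a class.

    A CMC must satisfy three positive rules — a nucleus with a well-defined
    margin, green signal above threshold, and a staining pattern consistent
    with the marker (Melan-A: predominantly cytoplasmic, uniform or
    punctate; S100B: cytoplasmic and/or nuclear) — and three negative rules:
    no red signal above threshold (red+green objects are 'dual', never
    CMCs), not anuclear debris, and not touching a FOV border.  Cell size is
    deliberately not a criterion.  Returns one of ``cmc, leukocyte, dual,
    null, debris, border``.
    """
    if cell.nucleus is None:
        return "debris"
    if cell.border:
        return "border"
    green_pos = cell.green_mean > thresholds.t_green
    red_pos = cell.red_mean > thresholds.t_red
    if green_pos and red_pos:
        return "dual"
    if red_pos:
        return "leukocyte"
    if not green_pos:
        return "null"
    # green-only object: apply nucleus-margin and pattern rules
    if cell.nucleus.margin_score < margin_min:
        return "null"
    cell.pattern_observed = (
        "punctate" if cell.green_cv > green_cv_punctate else "uniform"
    )
    if marker == "MelanA" and cell.green_mean <= cell.green_nuclear_mean:
        # Melan-A is cytoplasmic; predominantly nuclear green is not a CMC
        return "null"
    return "cmc"


# ---------------------------------------------------------------------------
# Debris and whole-slide counting


def _debris_count(fov: FOVImage, nuclei_mask: np.ndarray, config: CountConfig) -> int:
    """Count anuclear stain clusters (debris) in one FOV.

    Debris is any connected cluster of clearly suprathreshold green or red
    pixels that does not associate with a nucleus.
    """
    green = fov.channels["marker"]
    red = fov.channels["cd45"]
    sig = np.zeros(fov.shape, dtype=bool)
    for chan in (green, red):
        sig |= chan > _robust_noise_floor(chan, config.noise_floor_sigma)
    near_nucleus = morphology.dilation(
        nuclei_mask, morphology.disk(config.annulus_width + 2)
    )
    sig &= ~near_nucleus
    labels = measure.label(sig, connectivity=2)
    n = 0
    for props in measure.regionprops(labels):
        if props.area >= config.min_debris_area:
            n += 1
    return n


@dataclass
class CountResult:
    """Whole-slide counting output: tallies, thresholds, per-object table."""

    slide_count: SlideCount
    thresholds: ThresholdPair
    cells: pd.DataFrame


def _overlay(fov: FOVImage, cells: list[CellObject], labels: np.ndarray) -> np.ndarray:
    """RGB review image: channel merge with class-coded nucleus outlines."""
    rgb = np.stack(
        [fov.channels["cd45"], fov.channels["marker"], fov.channels["dapi"]], axis=-1
    ).astype(np.uint8)
    colors = {
        "cmc": (0, 255, 0),
        "leukocyte": (255, 0, 0),
        "dual": (255, 255, 0),
        "null": (160, 160, 160),
        "border": (255, 0, 255),
    }
    for cell in cells:
        if cell.nucleus is None:
            continue
        color = colors.get(cell.class_label, (255, 255, 255))
        r0, c0, r1, c1 = cell.nucleus.bbox
        win = (slice(max(r0 - 2, 0), min(r1 + 2, fov.shape[0])),
               slice(max(c0 - 2, 0), min(c1 + 2, fov.shape[1])))
        boundary = segmentation.find_boundaries(labels[win] == cell.nucleus.label,
                                                mode="outer")
        rgb[win][boundary] = color
    return rgb


def count_slide(
    slide: SlideImageSet,
    config: CountConfig | None = None,
    out_dir: str | Path | None = None,
) -> CountResult:
    """Run the full counting algorithm over every FOV of a slide.

    Segments nuclei, measures every cell, derives global thresholds from the
    pooled per-cell intensities (unless explicit thresholds are configured),
    classifies each object, and tallies the four classes plus debris and
    border objects.  When ``out_dir`` is given, writes one class-coded RGB
    overlay PNG per FOV for the manual review step.
    """
    config = config or CountConfig()
    per_fov: list[tuple[FOVImage, list[CellObject], np.ndarray]] = []
    n_debris = 0
    all_cells: list[CellObject] = []
    for fov in slide:
        try:
            nuclei, mask = nuclear_mask(fov.channels["dapi"], config, fov.fov_index)
            labels = measure.label(mask, connectivity=2)
            cells = [
                measure_cell(fov, nuc, mask, labels, config.annulus_width)
                for nuc in nuclei
            ]
            n_debris += _debris_count(fov, mask, config)
        except Exception as exc:  # annotate with the failing FOV
            raise type(exc)(f"FOV {fov.fov_index}: {exc}") from exc
        per_fov.append((fov, cells, labels))
        all_cells.extend(cells)

    if config.t_red is not None and config.t_green is not None:
        thresholds = select_thresholds([], mode="explicit",
                                       explicit=(config.t_red, config.t_green))
    elif not all_cells:
        thresholds = ThresholdPair(t_red=255.0, t_green=255.0, mode="explicit")
    else:
        thresholds = select_thresholds(
            all_cells, mode=config.threshold_mode, stringency=config.stringency
        )

    tally = {"cmc": 0, "leukocyte": 0, "dual": 0, "null": 0, "border": 0}
    for cell in all_cells:
        cell.class_label = classify_object(
            cell, thresholds, config.marker, config.margin_min, config.green_cv_punctate
        )
        tally[cell.class_label] += 1

    if out_dir is not None:
        import imageio.v3 as iio

        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for fov, cells, labels in per_fov:
            iio.imwrite(out_dir / f"overlay_fov{fov.fov_index:04d}.png",
                        _overlay(fov, cells, labels))

    slide_count = SlideCount(
        n_cmc_slide=tally["cmc"],
        n_leuko_slide=tally["leukocyte"],
        n_dual=tally["dual"],
        n_null=tally["null"],
        n_debris=n_debris,
        n_border=tally["border"],
    )
    rows = [
        {
            "fov_index": c.nucleus.fov_index if c.nucleus else -1,
            "row": c.nucleus.centroid[0] if c.nucleus else np.nan,
            "col": c.nucleus.centroid[1] if c.nucleus else np.nan,
            "area": c.nucleus.area if c.nucleus else np.nan,
            "margin_score": c.nucleus.margin_score if c.nucleus else np.nan,
            "green_mean": c.green_mean,
            "red_mean": c.red_mean,
            "green_nuclear_mean": c.green_nuclear_mean,
            "green_cv": c.green_cv,
            "pattern": c.pattern_observed,
            "class_label": c.class_label,
        }
        for c in all_cells
    ]
    cells_df = pd.DataFrame(
        rows,
        columns=["fov_index", "row", "col", "area", "margin_score", "green_mean",
                 "red_mean", "green_nuclear_mean", "green_cv", "pattern", "class_label"],
    )
    return CountResult(slide_count=slide_count, thresholds=thresholds, cells=cells_df)
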