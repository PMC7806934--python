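"""Per-cell immunofluorescence quantification.

The measurement chain mirrors the original plate-reader analysis: threshold
each channel, extract connected components, measure each blob's boundary
perimeter (µm) and interior mean grey value, keep blobs inside the capture
ranges (25–200 µm perimeter, 140–300 mean grey by default), pair green
marker blobs with the nearest red leukocyte blob (colocalization), call a
cell marker-positive when its green blob falls in the tighter positivity
ranges (25–150 µm, 150–280), and reduce the pooled cells of a sample to the
two screening statistics: average marker intensity and % positive cells.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from skimage.measure import label as _cc_label, regionprops

logger = logging.getLogger(__name__)

__all__ = [
    "QuantConfig",
    "DetectedSignal",
    "CellRecord",
    "SampleResult",
    "detect_signals",
    "colocalize",
    "classify_positive",
    "summarize_sample",
    "quantify_well",
    "interassay_adjust",
]


@dataclass(frozen=True)
class QuantConfig:
    """Thresholds and filter ranges for blob detection and positivity calls.

    All range bounds are inclusive. ``detection_threshold`` defaults to the
    capture-intensity lower bound; the binarization threshold of the original
    software is not published. ``intensity_stat_mode`` selects the per-sample
    average-intensity definition (see :func:`summarize_sample`).
    """

    um_per_px: float = 0.65
    detection_threshold: float = 140.0
    capture_perimeter_range: tuple[float, float] = (25.0, 200.0)
    capture_intensity_range: tuple[float, float] = (140.0, 300.0)
    positive_perimeter_range: tuple[float, float] = (25.0, 150.0)
    positive_intensity_range: tuple[float, float] = (150.0, 280.0)
    coloc_max_centroid_dist_um: float = 5.0
    intensity_stat_mode: str = "mean_of_positives"

    def __post_init__(self) -> None:
        if self.um_per_px <= 0:
            raise ValueError("um_per_px must be > 0")
        for name in (
            "capture_perimeter_range",
            "capture_intensity_range",
            "positive_perimeter_range",
            "positive_intensity_range",
        ):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} must be ordered min <= max")
        if self.coloc_max_centroid_dist_um <= 0:
            raise ValueError("coloc_max_centroid_dist_um must be > 0")
        if self.intensity_stat_mode not in ("ratio_as_stated", "mean_of_positives"):
            raise ValueError(
                "intensity_stat_mode must be 'ratio_as_stated' or "
                "'mean_of_positives'"
            )


@dataclass(frozen=True)
class DetectedSignal:
    """One measured blob on one channel.

    ``x``/``y`` are the intensity-unweighted centroid in pixels (x = column,
    y = row); ``perimeter_um`` is the Crofton-corrected boundary length
    scaled by the µm-per-pixel calibration; ``mean_grey`` is the mean pixel
    value inside the component.
    """

    channel: str
    x: float
    y: float
    area_px: int
    perimeter_um: float
    mean_grey: float


@dataclass
class CellRecord:
    """One leukocyte: its red signal, an optional colocalized green marker
    signal, and the positivity call."""

    red_signal: DetectedSignal
    green_signal: DetectedSignal | None = None
    is_positive: bool = False


@dataclass
class SampleResult:
    """Per-sample screening statistics pooled over a well's fields.

    ``avg_intensity`` follows ``intensity_mode``; ``stats_defined`` is False
    (and the statistics NaN) when no cells — or, for the mean-of-positives
    mode, no positive cells — were found.
    """

    sample_id: str
    n_cells: int
    n_positive: int
    avg_intensity: float
    pct_positive: float
    intensity_mode: str
    stats_defined: bool
    group_label: str | None = None

    def as_dict(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "group": self.group_label,
            "n_cells": self.n_cells,
            "n_positive": self.n_positive,
            "avg_intensity": self.avg_intensity,
            "pct_positive": self.pct_positive,
            "intensity_mode": self.intensity_mode,
            "stats_defined": self.stats_defined,
        }


def _in_range(value: float, bounds: tuple[float, float]) -> bool:
    return bounds[0] <= value <= bounds[1]


def detect_signals(
    channel_image: np.ndarray,
    config: QuantConfig,
    channel: str = "green",
    detection_threshold: float | None = None,
) -> list[DetectedSignal]:
    """Detect and measure blobs on a single channel.

    Pixels at or above the detection threshold form 8-connected components;
    each component's perimeter (Crofton estimate x ``um_per_px``) and mean
    grey value are measured, and only components inside both inclusive
    capture ranges are returned, sorted by (y, x) centroid. An image with no
    signal yields an empty list.
    """
    image = np.asarray(channel_image)
    if image.ndim != 2:
        raise ValueError("channel image must be 2-D")
    thr = config.detection_threshold if detection_threshold is None else detection_threshold
    mask = image >= thr
    if not mask.any():
        return []
    labelled = _cc_label(mask, connectivity=2)
    signals = []
    for rp in regionprops(labelled, intensity_image=image):
        perimeter_um = rp.perimeter_crofton * config.um_per_px
        mean_grey = float(rp.intensity_mean)
        if not _in_range(perimeter_um, config.capture_perimeter_range):
            continue
        if not _in_range(mean_grey, config.capture_intensity_range):
            continue
        cy, cx = rp.centroid
        signals.append(
            DetectedSignal(
                channel=channel,
                x=float(cx),
                y=float(cy),
                area_px=int(rp.area),
                perimeter_um=float(perimeter_um),
                mean_grey=mean_grey,
            )
        )
    signals.sort(key=lambda s: (s.y, s.x))
    return signals


def colocalize(
    red: Sequence[DetectedSignal],
    green: Sequence[DetectedSignal],
    config: QuantConfig,
) -> list[CellRecord]:
    """Pair green marker blobs with red leukocyte blobs by centroid distance.

    Greedy matching: the globally closest remaining (green, red) pair within
    ``coloc_max_centroid_dist_um`` is assigned first, then the next, each
    signal used at most once; ties break by (y, x) order of the signals.
    Every red signal yields one :class:`CellRecord`; green signals left
    unmatched are discarded with a logged count.
    """
    red = sorted(red, key=lambda s: (s.y, s.x))
    green = sorted(green, key=lambda s: (s.y, s.x))
    records = [CellRecord(red_signal=r) for r in red]
    if red and green:
        max_dist = config.coloc_max_centroid_dist_um
        pairs = []
        for gi, g in enumerate(green):
            for ri, r in enumerate(red):
                d = math.hypot(g.x - r.x, g.y - r.y) * config.um_per_px
                if d <= max_dist:
                    pairs.append((d, gi, ri))
        pairs.sort()
        used_green: set[int] = set()
        used_red: set[int] = set()
        for d, gi, ri in pairs:
            if gi in used_green or ri in used_red:
                continue
            used_green.add(gi)
            used_red.add(ri)
            records[ri].green_signal = green[gi]
    else:
        used_green = set()
    n_discarded = len(green) - len(used_green)
    if n_discarded:
        logger.info(
            "colocalize: discarded %d green signal(s) with no red partner "
            "within %.2f um",
            n_discarded,
            config.coloc_max_centroid_dist_um,
        )
    return records


def classify_positive(record: CellRecord, config: QuantConfig) -> CellRecord:
    """Set the positivity flag: a cell is marker-positive iff it carries a
    colocalized green signal whose perimeter and mean grey value fall inside
    the inclusive positivity ranges."""
    g = record.green_signal
    record.is_positive = bool(
        g is not None
        and _in_range(g.perimeter_um, config.positive_perimeter_range)
        and _in_range(g.mean_grey, config.positive_intensity_range)
    )
    return record


def summarize_sample(
    records: Sequence[CellRecord],
    config: QuantConfig,
    sample_id: str = "sample",
    group_label: str | None = None,
) -> SampleResult:
    """Reduce pooled cell records to the two per-sample screening statistics.

    ``pct_positive`` is 100 x n_positive / n_cells.  ``avg_intensity``
    depends on the configured mode:

    * ``mean_of_positives`` (default) — arithmetic mean of the green mean
      grey value over positive cells; on the grey-value scale of the
      published cohort summaries.
    * ``ratio_as_stated`` — sum of green mean grey over positive cells
      divided by the sum over all cells (cells without a green signal
      contribute zero), the screening protocol's literal formula; a
      dimensionless value <= 1 when negatives carry no green signal.

    Zero cells (or, in mean-of-positives mode, zero positives) leaves the
    affected statistics NaN with ``stats_defined`` False rather than raising.
    """
    n_cells = len(records)
    n_positive = sum(1 for r in records if r.is_positive)
    mode = config.intensity_stat_mode
    if n_cells == 0:
        return SampleResult(
            sample_id, 0, 0, float("nan"), float("nan"), mode, False, group_label
        )
    pct = 100.0 * n_positive / n_cells
    pos_grey = [r.green_signal.mean_grey for r in records if r.is_positive]
    all_grey = [
        r.green_signal.mean_grey if r.green_signal is not None else 0.0
        for r in records
    ]
    if mode == "mean_of_positives":
        if n_positive == 0:
            return SampleResult(
                sample_id, n_cells, 0, float("nan"), pct, mode, False, group_label
            )
        avg = float(np.mean(pos_grey))
    else:
        denom = float(np.sum(all_grey))
        if denom == 0.0:
            return SampleResult(
                sample_id, n_cells, n_positive, float("nan"), pct, mode, False,
                group_label,
            )
        avg = float(np.sum(pos_grey)) / denom
    return SampleResult(
        sample_id, n_cells, n_positive, avg, pct, mode, True, group_label
    )


def quantify_well(
    field_images: Iterable,
    config: QuantConfig,
    sample_id: str = "sample",
    group_label: str | None = None,
) -> SampleResult:
    """Run the full per-field chain and pool one well into a SampleResult.

    Accepts 1–12 :class:`~lymphoscreen.simulate.FieldImage`-like objects
    (anything with ``red``/``green`` arrays and ``um_per_px``). Per field:
    detect red and green signals, colocalize, classify; the cell records of
    all fields are pooled before summarizing, so field order does not matter.
    """
    fields = list(field_images)
    if not fields:
        raise ValueError("at least one field image is required")
    if len(fields) > 12:
        raise ValueError("a well has at most 12 fields")
    records: list[CellRecord] = []
    for fld in fields:
        cfg = config
        um = getattr(fld, "um_per_px", None)
        if um is not None and um != config.um_per_px:
            cfg = replace(config, um_per_px=um)
        red = detect_signals(fld.red, cfg, channel="red")
        green = detect_signals(fld.green, cfg, channel="green")
        cells = colocalize(red, green, cfg)
        records.extend(classify_positive(c, cfg) for c in cells)
    return summarize_sample(records, config, sample_id, group_label)


def interassay_adjust(
    intensities: Mapping[str, Sequence[float]] | Sequence[float],
    batch_control: Mapping[str, float] | float,
    reference_control: float,
) -> dict[str, np.ndarray] | np.ndarray:
    """Multiplicative between-batch rescaling anchored on a shared control.

    Each batch's intensities are multiplied by
    ``reference_control / batch_control`` so the positive-control sample
    (a cocultured-PBMC well measured in every batch) lands on the same value
    everywhere. Accepts either a single batch (sequence + scalar control) or
    a mapping of batch id -> values with per-batch controls.
    """
    if reference_control <= 0:
        raise ValueError("reference_control must be > 0")
    if isinstance(intensities, Mapping):
        if not isinstance(batch_control, Mapping):
            raise TypeError("batch_control must be a mapping when batches are")
        out = {}
        for batch, values in intensities.items():
            ctrl = batch_control[batch]
            if ctrl <= 0:
                raise ValueError(f"control intensity for batch {batch!r} must be > 0")
            out[batch] = np.asarray(values, dtype=float) * (reference_control / ctrl)
        return out
    ctrl = float(batch_control)  # type: ignore[arg-type]
    if ctrl <= 0:
        raise ValueError("batch control intensity must be > 0")
    return np.asarray(intensities, dtype=float) * (reference_control / ctrl)
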