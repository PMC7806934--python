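"""Synthetic inputs for the screening pipeline.

Three generators cover everything the downstream modules consume:

* :func:`generate_field_image` — a calibrated 3-channel microscopy field
  (nuclear/blue, pan-leukocyte/red, marker/green) with disk-shaped cells and
  a ground-truth table, standing in for stained-well acquisitions.
* :func:`generate_cohort` — a two-group screening cohort of per-sample
  (average marker intensity, % marker-positive cells) pairs with the
  published group means/SDs and a strong linear correlation between the two
  statistics.
* :func:`generate_expression_pair` — two case/control expression studies
  over a shared gene universe with a planted set of jointly up-regulated
  genes, plus a fixed candidate gene list.

All generators are deterministic given their ``seed``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from skimage.draw import disk as _disk_coords

from .intersect import ExpressionStudy

__all__ = [
    "IntensityLaw",
    "ImageSimConfig",
    "FieldImage",
    "GroupParams",
    "CohortSimParams",
    "ExpressionSimParams",
    "generate_field_image",
    "generate_well_fields",
    "generate_cohort",
    "generate_expression_pair",
]


# ---------------------------------------------------------------------------
# intensity distributions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class IntensityLaw:
    """Per-cell grey-value distribution: ``constant``, ``uniform`` or ``normal``.

    Parameters are ``(value,)``, ``(low, high)`` or ``(mean, sd)`` in grey
    units; samples are truncated below at zero.
    """

    name: str
    params: tuple[float, ...]

    def __post_init__(self) -> None:
        expected = {"constant": 1, "uniform": 2, "normal": 2}
        if self.name not in expected:
            raise ValueError(f"unknown intensity law {self.name!r}")
        if len(self.params) != expected[self.name]:
            raise ValueError(
                f"law {self.name!r} needs {expected[self.name]} parameter(s)"
            )
        if self.name == "uniform" and self.params[0] > self.params[1]:
            raise ValueError("uniform law needs low <= high")

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if self.name == "constant":
            out = np.full(size, float(self.params[0]))
        elif self.name == "uniform":
            out = rng.uniform(self.params[0], self.params[1], size)
        else:
            out = rng.normal(self.params[0], self.params[1], size)
        return np.clip(out, 0.0, None)


# ---------------------------------------------------------------------------
# field-image simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ImageSimConfig:
    """Acquisition geometry and per-cell signal laws for one simulated field."""

    field_width_px: int = 512
    field_height_px: int = 512
    um_per_px: float = 0.65
    n_cells: int = 60
    positive_fraction: float = 0.5
    radius_range_um: tuple[float, float] = (5.0, 12.0)
    intensity_law_red: IntensityLaw = field(
        default_factory=lambda: IntensityLaw("uniform", (170.0, 250.0))
    )
    intensity_law_green: IntensityLaw = field(
        default_factory=lambda: IntensityLaw("uniform", (170.0, 250.0))
    )
    intensity_law_blue: IntensityLaw = field(
        default_factory=lambda: IntensityLaw("uniform", (170.0, 250.0))
    )
    background_noise_sd: float = 2.0
    bit_depth: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.field_width_px <= 0 or self.field_height_px <= 0:
            raise ValueError("field dimensions must be positive")
        if self.um_per_px <= 0:
            raise ValueError("um_per_px must be > 0")
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        if not 0.0 <= self.positive_fraction <= 1.0:
            raise ValueError("positive_fraction must lie in [0, 1]")
        lo, hi = self.radius_range_um
        if lo <= 0 or hi <= 0 or lo > hi:
            raise ValueError("radius range must be positive with min <= max")
        if self.background_noise_sd < 0:
            raise ValueError("background_noise_sd must be >= 0")
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")


@dataclass
class FieldImage:
    """One calibrated field: three single-channel arrays plus µm/pixel scale.

    ``exposure_ms`` is carried as annotation only; no photometric correction
    is derived from it.
    """

    blue: np.ndarray
    red: np.ndarray
    green: np.ndarray
    um_per_px: float
    exposure_ms: dict[str, float] | None = None

    @property
    def shape(self) -> tuple[int, int]:
        return self.blue.shape

    def channel(self, name: str) -> np.ndarray:
        try:
            return {"blue": self.blue, "red": self.red, "green": self.green}[name]
        except KeyError:
            raise KeyError(f"unknown channel {name!r}") from None


def _place_cells(
    rng: np.random.Generator,
    config: ImageSimConfig,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample non-overlapping centres and radii (both in px).

    Disks are rejected if two centres come closer than the sum of their radii
    plus a 2 px guard, so rasterized components never touch and ground-truth
    blobs map one-to-one onto connected components.
    """
    h, w = config.field_height_px, config.field_width_px
    lo_px = config.radius_range_um[0] / config.um_per_px
    hi_px = config.radius_range_um[1] / config.um_per_px
    centres: list[tuple[float, float]] = []
    radii: list[float] = []
    max_attempts = 2000 * max(config.n_cells, 1)
    attempts = 0
    while len(centres) < config.n_cells:
        if attempts >= max_attempts:
            raise RuntimeError(
                f"could not place {config.n_cells} non-overlapping cells in a "
                f"{w}x{h} px field; reduce n_cells or the radius range"
            )
        attempts += 1
        r = rng.uniform(lo_px, hi_px)
        margin = r + 1.0
        if 2 * margin >= min(h, w):
            raise RuntimeError("cell radius too large for the field")
        y = rng.uniform(margin, h - margin)
        x = rng.uniform(margin, w - margin)
        ok = all(
            math.hypot(y - yc, x - xc) >= r + rc + 2.0
            for (yc, xc), rc in zip(centres, radii)
        )
        if ok:
            centres.append((y, x))
            radii.append(r)
    return np.asarray(centres, dtype=float).reshape(-1, 2), np.asarray(radii)


def generate_field_image(config: ImageSimConfig) -> tuple[FieldImage, pd.DataFrame]:
    """Render one field and its ground truth.

    Every planted cell is a filled disk with uniform interior intensity on
    the blue and red channels; a ``round(positive_fraction * n_cells)``
    subset also carries a green disk at the same centroid (the
    marker-positive cells). Uniform disks make the true perimeter (2πr) and
    the true mean grey value analytically known, which is what the
    quantification oracle tests rely on.

    Returns the image and a ground-truth table with one row per planted
    cell: ``centroid_x``/``centroid_y`` (px), ``radius_um``,
    ``perimeter_um`` (= 2πr), per-channel mean grey values and
    ``is_marker_positive``.
    """
    rng = np.random.default_rng(config.seed)
    h, w = config.field_height_px, config.field_width_px
    max_val = float(2**config.bit_depth - 1)

    centres, radii_px = _place_cells(rng, config)
    n = config.n_cells
    n_positive = int(round(config.positive_fraction * n))
    is_positive = np.zeros(n, dtype=bool)
    if n:
        is_positive[rng.permutation(n)[:n_positive]] = True

    blue_grey = np.clip(config.intensity_law_blue.sample(rng, n), 0, max_val)
    red_grey = np.clip(config.intensity_law_red.sample(rng, n), 0, max_val)
    green_grey = np.where(
        is_positive, np.clip(config.intensity_law_green.sample(rng, n), 0, max_val), 0.0
    )

    channels = {
        "blue": np.zeros((h, w), dtype=float),
        "red": np.zeros((h, w), dtype=float),
        "green": np.zeros((h, w), dtype=float),
    }
    for i in range(n):
        rr, cc = _disk_coords(tuple(centres[i]), radii_px[i], shape=(h, w))
        channels["blue"][rr, cc] = blue_grey[i]
        channels["red"][rr, cc] = red_grey[i]
        if is_positive[i]:
            channels["green"][rr, cc] = green_grey[i]

    dtype = np.uint8 if config.bit_depth == 8 else np.uint16
    for name in channels:
        img = channels[name]
        if config.background_noise_sd > 0:
            img = img + rng.normal(0.0, config.background_noise_sd, size=(h, w))
        channels[name] = np.clip(np.rint(img), 0, max_val).astype(dtype)

    truth = pd.DataFrame(
        {
            "centroid_x": centres[:, 1] if n else np.empty(0),
            "centroid_y": centres[:, 0] if n else np.empty(0),
            "radius_um": radii_px * config.um_per_px,
            "perimeter_um": 2 * np.pi * radii_px * config.um_per_px,
            "mean_blue": blue_grey,
            "mean_red": red_grey,
            "mean_green": green_grey,
            "is_marker_positive": is_positive,
        }
    )
    image = FieldImage(
        blue=channels["blue"],
        red=channels["red"],
        green=channels["green"],
        um_per_px=config.um_per_px,
        exposure_ms={"blue": 25.5, "red": 700.0, "green": 316.0},
    )
    return image, truth


def generate_well_fields(
    config: ImageSimConfig, n_fields: int = 12
) -> tuple[list[FieldImage], pd.DataFrame]:
    """Simulate one well as ``n_fields`` independent fields (default 12,
    mirroring a 4x3 grid of 20x fields per well) with pooled ground truth.

    Field ``i`` uses seed ``config.seed + i``; the pooled truth table gains a
    ``field`` column.
    """
    if n_fields < 1:
        raise ValueError("n_fields must be >= 1")
    images, truths = [], []
    for i in range(n_fields):
        cfg = ImageSimConfig(**{**config.__dict__, "seed": config.seed + i})
        img, truth = generate_field_image(cfg)
        truth.insert(0, "field", i + 1)
        images.append(img)
        truths.append(truth)
    return images, pd.concat(truths, ignore_index=True)


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GroupParams:
    """Target moments of one group's (intensity, % positive) distribution."""

    mean_intensity: float
    sd_intensity: float
    mean_pct: float
    sd_pct: float

    def __post_init__(self) -> None:
        if self.sd_intensity <= 0 or self.sd_pct <= 0:
            raise ValueError("SDs must be > 0")


#: Published cohort moments: average marker fluorescence intensity and
#: % marker-positive lymphocytes, breast-cancer patients vs healthy females.
CANCER_GROUP = GroupParams(110.50, 23.38, 61.87, 12.44)
NORMAL_GROUP = GroupParams(56.47, 32.03, 33.02, 18.10)


@dataclass(frozen=True)
class CohortSimParams:
    """Two-group cohort of (avg_intensity, pct_positive) sample pairs.

    The configured means/SDs are the moments of the *truncated* sampling law
    (intensity >= 0, pct in [0, 100]); underlying bivariate-normal parameters
    are calibrated by moment matching so large-sample statistics reproduce
    them. ``rho`` is the underlying correlation between the two statistics.
    """

    cancer: GroupParams = field(default_factory=lambda: CANCER_GROUP)
    normal: GroupParams = field(default_factory=lambda: NORMAL_GROUP)
    rho: float = 0.95
    n_cancer: int = 358
    n_normal: int = 363
    n_replicate_sets: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not -1.0 < self.rho < 1.0:
            raise ValueError("rho must lie in (-1, 1)")
        if self.n_cancer < 0 or self.n_normal < 0:
            raise ValueError("sample counts must be >= 0")
        if self.n_replicate_sets is not None and self.n_replicate_sets < 1:
            raise ValueError("n_replicate_sets must be >= 1 when given")


def _truncated_mvn_moments(
    mx: float, my: float, sx: float, sy: float, rho: float,
    bounds: tuple[tuple[float, float], tuple[float, float]],
    n_nodes: int = 64,
) -> tuple[float, float, float, float]:
    """Mean and SD of each coordinate of a bivariate normal restricted to a
    rectangle, by tensor-product Gauss–Legendre quadrature."""
    (lx, ux), (ly, uy) = bounds
    lx, ux = max(lx, mx - 9 * sx), min(ux, mx + 9 * sx)
    ly, uy = max(ly, my - 9 * sy), min(uy, my + 9 * sy)
    xn, xw = np.polynomial.legendre.leggauss(n_nodes)
    gx = 0.5 * (ux - lx) * xn + 0.5 * (ux + lx)
    wx = 0.5 * (ux - lx) * xw
    gy = 0.5 * (uy - ly) * xn + 0.5 * (uy + ly)
    wy = 0.5 * (uy - ly) * xw
    X, Y = np.meshgrid(gx, gy, indexing="ij")
    cov = np.array([[sx**2, rho * sx * sy], [rho * sx * sy, sy**2]])
    pdf = stats.multivariate_normal([mx, my], cov).pdf(np.dstack([X, Y]))
    W = np.outer(wx, wy) * pdf
    z = W.sum()
    ex = (W * X).sum() / z
    ey = (W * Y).sum() / z
    vx = (W * (X - ex) ** 2).sum() / z
    vy = (W * (Y - ey) ** 2).sum() / z
    return ex, ey, math.sqrt(vx), math.sqrt(vy)


@lru_cache(maxsize=64)
def _calibrated_params(
    mean_x: float, sd_x: float, mean_y: float, sd_y: float, rho: float
) -> tuple[float, float, float, float]:
    """Underlying (mx, my, sx, sy) whose rectangle-truncated law (x >= 0,
    y in [0, 100]) has the requested means and SDs."""
    bounds = ((0.0, np.inf), (0.0, 100.0))

    def residual(theta: np.ndarray) -> np.ndarray:
        mx, my, lsx, lsy = theta
        ex, ey, ox, oy = _truncated_mvn_moments(
            mx, my, math.exp(lsx), math.exp(lsy), rho, bounds
        )
        return np.array([ex - mean_x, ey - mean_y, ox - sd_x, oy - sd_y])

    x0 = np.array([mean_x, mean_y, math.log(sd_x), math.log(sd_y)])
    sol = optimize.root(residual, x0, method="hybr", tol=1e-10)
    if not sol.success:  # pragma: no cover - well-conditioned in practice
        raise RuntimeError(f"moment calibration failed: {sol.message}")
    mx, my, lsx, lsy = sol.x
    return float(mx), float(my), float(math.exp(lsx)), float(math.exp(lsy))


def _sample_truncated_pairs(
    rng: np.random.Generator, group: GroupParams, rho: float, n: int
) -> np.ndarray:
    """Draw n (intensity, pct) pairs by resampling out-of-range rows.

    Resampling (rather than clipping) keeps the truncated law smooth at the
    boundaries so the calibrated moments hold.
    """
    mx, my, sx, sy = _calibrated_params(
        group.mean_intensity, group.sd_intensity, group.mean_pct, group.sd_pct, rho
    )
    cov = np.array([[sx**2, rho * sx * sy], [rho * sx * sy, sy**2]])
    chol = np.linalg.cholesky(cov)
    out = np.empty((n, 2))
    filled = 0
    while filled < n:
        need = n - filled
        z = rng.standard_normal((max(2 * need, 16), 2))
        draws = np.array([mx, my]) + z @ chol.T
        keep = (draws[:, 0] >= 0) & (draws[:, 1] >= 0) & (draws[:, 1] <= 100)
        accepted = draws[keep][:need]
        out[filled : filled + len(accepted)] = accepted
        filled += len(accepted)
    return out


def generate_cohort(params: CohortSimParams) -> pd.DataFrame:
    """Simulate a two-group screening cohort.

    Returns a table with columns ``sample_id, group, avg_intensity,
    pct_positive, n_cells, n_positive`` (and ``replicate_set`` when
    ``n_replicate_sets`` is set); one row per sample, group labels
    ``cancer`` / ``normal``. Cell counts per sample are drawn uniformly in
    [300, 700] and ``n_positive`` is the rounded pct share, so the count
    columns are consistent with the percentage.
    """
    rng = np.random.default_rng(params.seed)
    frames = []
    for label, group, n in (
        ("cancer", params.cancer, params.n_cancer),
        ("normal", params.normal, params.n_normal),
    ):
        pairs = _sample_truncated_pairs(rng, group, params.rho, n)
        n_cells = rng.integers(300, 701, size=n)
        n_pos = np.rint(pairs[:, 1] / 100.0 * n_cells).astype(int)
        frames.append(
            pd.DataFrame(
                {
                    "sample_id": [f"{label}_{i + 1:04d}" for i in range(n)],
                    "group": label,
                    "avg_intensity": pairs[:, 0],
                    "pct_positive": pairs[:, 1],
                    "n_cells": n_cells,
                    "n_positive": n_pos,
                }
            )
        )
    cohort = pd.concat(frames, ignore_index=True)
    if params.n_replicate_sets is not None:
        cohort["replicate_set"] = (
            rng.integers(1, params.n_replicate_sets + 1, size=len(cohort))
        )
    return cohort


# ---------------------------------------------------------------------------
# paired expression studies
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ExpressionSimParams:
    """Two case/control studies over one gene universe with planted signal.

    ``n_shared_up`` genes are shifted up in cases of both studies by
    ``effect_size * noise_sd``; ``n_study_specific_up`` genes per study shift
    in that study only; the rest are null. ``list_size`` / ``list_enrichment``
    control the companion fixed gene list: an ``enrichment`` fraction of the
    list is drawn from the planted shared genes, the rest from null genes.
    """

    n_genes: int = 1000
    n_samples_per_group: int = 20
    n_shared_up: int = 50
    n_study_specific_up: int = 50
    effect_size: float = 2.0
    noise_sd: float = 1.0
    list_size: int = 100
    list_enrichment: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_genes, self.n_samples_per_group) <= 0:
            raise ValueError("n_genes and n_samples_per_group must be positive")
        if self.n_shared_up < 0 or self.n_study_specific_up < 0:
            raise ValueError("planted gene counts must be >= 0")
        if self.n_shared_up + 2 * self.n_study_specific_up > self.n_genes:
            raise ValueError("planted gene sets exceed the gene universe")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if not 0.0 <= self.list_enrichment <= 1.0:
            raise ValueError("list_enrichment must lie in [0, 1]")
        if self.list_size > self.n_genes:
            raise ValueError("list_size exceeds the gene universe")


def _make_study(
    rng: np.random.Generator,
    genes: Sequence[str],
    up_idx: np.ndarray,
    params: ExpressionSimParams,
) -> ExpressionStudy:
    n_g, n_s = params.n_genes, params.n_samples_per_group
    matrix = rng.normal(0.0, params.noise_sd, size=(n_g, 2 * n_s))
    matrix[up_idx, :n_s] += params.effect_size * params.noise_sd
    labels = ["case"] * n_s + ["control"] * n_s
    return ExpressionStudy(
        gene_ids=list(genes), matrix=matrix, group_labels=labels
    )


def generate_expression_pair(
    params: ExpressionSimParams,
) -> tuple[ExpressionStudy, ExpressionStudy, dict[str, list[str]]]:
    """Simulate the paired-study marker-discovery input.

    Returns two studies plus the planted truth: ``shared_up`` (up in both),
    ``study_a_only_up`` / ``study_b_only_up``, and ``gene_list`` (the fixed
    candidate list enriched for the shared genes).
    """
    rng = np.random.default_rng(params.seed)
    genes = [f"G{i + 1:05d}" for i in range(params.n_genes)]
    order = rng.permutation(params.n_genes)
    n_sh, n_sp = params.n_shared_up, params.n_study_specific_up
    shared = order[:n_sh]
    a_only = order[n_sh : n_sh + n_sp]
    b_only = order[n_sh + n_sp : n_sh + 2 * n_sp]
    null = order[n_sh + 2 * n_sp :]

    study_a = _make_study(rng, genes, np.concatenate([shared, a_only]), params)
    study_b = _make_study(rng, genes, np.concatenate([shared, b_only]), params)

    n_from_planted = min(int(round(params.list_enrichment * params.list_size)), n_sh)
    n_from_null = min(params.list_size - n_from_planted, len(null))
    list_idx = np.concatenate(
        [
            rng.choice(shared, size=n_from_planted, replace=False)
            if n_from_planted
            else np.empty(0, dtype=int),
            rng.choice(null, size=n_from_null, replace=False)
            if n_from_null
            else np.empty(0, dtype=int),
        ]
    ).astype(int)

    truth = {
        "shared_up": sorted(genes[i] for i in shared),
        "study_a_only_up": sorted(genes[i] for i in a_only),
        "study_b_only_up": sorted(genes[i] for i in b_only),
        "gene_list": sorted(genes[i] for i in list_idx),
    }
    return study_a, study_b, truth
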