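"""File formats: field TIFFs, cohort/result CSVs, expression TSVs, gene lists.

Field images travel either as one 3-page TIFF (pages ordered blue, red,
green) or as three per-channel files named ``<well>_f<NN>_<channel>.tif``;
cohorts and per-sample results as CSV with the documented header
``sample_id, group, avg_intensity, pct_positive, n_cells, n_positive``;
expression studies as TSV (genes x samples) whose first row carries the
case/control group labels; gene lists as plain text, one symbol per line.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

from .intersect import ExpressionStudy
from .quantify import SampleResult
from .simulate import FieldImage

__all__ = [
    "write_field_tiff",
    "read_field_tiff",
    "write_field_channels",
    "read_well_fields",
    "write_cohort_csv",
    "read_cohort_csv",
    "write_sample_results_csv",
    "write_expression_tsv",
    "read_expression_tsv",
    "write_gene_list",
    "read_gene_list",
]

_CHANNEL_ORDER = ("blue", "red", "green")
_FIELD_FILE_RE = re.compile(
    r"^(?P<well>[A-H]\d{1,2})_f(?P<field>\d{2})_(?P<channel>blue|red|green)\.tiff?$"
)


# --- TIFF fields -----------------------------------------------------------


def write_field_tiff(path: str | Path, image: FieldImage) -> None:
    """Write one field as a 3-page TIFF (blue, red, green), recording the
    µm-per-pixel calibration in the TIFF resolution tags."""
    stack = np.stack([image.channel(c) for c in _CHANNEL_ORDER])
    px_per_um = 1.0 / image.um_per_px
    tifffile.imwrite(
        str(path),
        stack,
        photometric="minisblack",
        resolution=(px_per_um, px_per_um),
        resolutionunit="MICROMETER",
    )


def read_field_tiff(path: str | Path, um_per_px: float | None = None) -> FieldImage:
    """Read a 3-page field TIFF; calibration comes from the resolution tags
    unless overridden (missing tags with no override is an error)."""
    with tifffile.TiffFile(str(path)) as tif:
        stack = tif.asarray()
        if um_per_px is None:
            page = tif.pages[0]
            res = page.tags.get("XResolution")
            unit = page.tags.get("ResolutionUnit")
            if res is None or unit is None or getattr(unit.value, "name", "") not in (
                "MICROMETER",
            ):
                raise ValueError(
                    f"{path}: no µm-per-pixel calibration in the TIFF; pass um_per_px"
                )
            num, den = res.value
            um_per_px = den / num
    if stack.ndim != 3 or stack.shape[0] != 3:
        raise ValueError(f"{path}: expected a 3-page (blue, red, green) TIFF")
    return FieldImage(
        blue=stack[0], red=stack[1], green=stack[2], um_per_px=float(um_per_px)
    )


def write_field_channels(
    directory: str | Path, well: str, field_no: int, image: FieldImage
) -> list[Path]:
    """Write one field as three per-channel TIFFs named
    ``<well>_f<NN>_<channel>.tif``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    px_per_um = 1.0 / image.um_per_px
    paths = []
    for channel in _CHANNEL_ORDER:
        path = directory / f"{well}_f{field_no:02d}_{channel}.tif"
        tifffile.imwrite(
            str(path),
            image.channel(channel),
            resolution=(px_per_um, px_per_um),
            resolutionunit="MICROMETER",
        )
        paths.append(path)
    return paths


def read_well_fields(
    directory: str | Path, um_per_px: float | None = None
) -> dict[str, list[FieldImage]]:
    """Collect per-channel field TIFFs from a directory into wells.

    Returns ``{well: [FieldImage, ...]}`` with fields in field-number order;
    every field must have all three channels.
    """
    directory = Path(directory)
    found: dict[tuple[str, int], dict[str, Path]] = {}
    for path in sorted(directory.iterdir()):
        m = _FIELD_FILE_RE.match(path.name)
        if not m:
            continue
        key = (m["well"], int(m["field"]))
        found.setdefault(key, {})[m["channel"]] = path
    if not found:
        raise ValueError(f"no per-channel field TIFFs found in {directory}")
    wells: dict[str, list[FieldImage]] = {}
    for (well, field_no), channels in sorted(found.items()):
        missing = set(_CHANNEL_ORDER) - set(channels)
        if missing:
            raise ValueError(
                f"well {well} field {field_no}: missing channel(s) {sorted(missing)}"
            )
        arrays = {}
        scale = um_per_px
        for channel in _CHANNEL_ORDER:
            with tifffile.TiffFile(str(channels[channel])) as tif:
                arrays[channel] = tif.asarray()
                if scale is None:
                    page = tif.pages[0]
                    res = page.tags.get("XResolution")
                    unit = page.tags.get("ResolutionUnit")
                    if res is not None and getattr(
                        getattr(unit, "value", None), "name", ""
                    ) == "MICROMETER":
                        num, den = res.value
                        scale = den / num
        if scale is None:
            raise ValueError(
                f"well {well}: no calibration in TIFF tags; pass um_per_px"
            )
        wells.setdefault(well, []).append(
            FieldImage(
                blue=arrays["blue"],
                red=arrays["red"],
                green=arrays["green"],
                um_per_px=float(scale),
            )
        )
    return wells


# --- cohort / per-sample CSV ----------------------------------------------

_COHORT_COLUMNS = [
    "sample_id",
    "group",
    "avg_intensity",
    "pct_positive",
    "n_cells",
    "n_positive",
]


def write_cohort_csv(path: str | Path, cohort: pd.DataFrame) -> None:
    missing = set(_COHORT_COLUMNS) - set(cohort.columns)
    if missing:
        raise ValueError(f"cohort is missing columns: {sorted(missing)}")
    cohort.to_csv(path, index=False)


def read_cohort_csv(path: str | Path) -> pd.DataFrame:
    cohort = pd.read_csv(path)
    missing = set(_COHORT_COLUMNS) - set(cohort.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if cohort["sample_id"].duplicated().any():
        raise ValueError(f"{path}: duplicated sample_id values")
    return cohort


def write_sample_results_csv(
    path: str | Path, results: Sequence[SampleResult]
) -> None:
    pd.DataFrame([r.as_dict() for r in results]).to_csv(path, index=False)


# --- expression TSV / gene lists ------------------------------------------


def write_expression_tsv(path: str | Path, study: ExpressionStudy) -> None:
    """Genes x samples TSV; the first data row holds the group labels."""
    with open(path, "w") as fh:
        n = study.matrix.shape[1]
        fh.write("gene_id\t" + "\t".join(f"S{i + 1}" for i in range(n)) + "\n")
        fh.write("__group__\t" + "\t".join(study.group_labels) + "\n")
        for gene, row in zip(study.gene_ids, study.matrix):
            fh.write(gene + "\t" + "\t".join(f"{v:.6g}" for v in row) + "\n")


def read_expression_tsv(path: str | Path) -> ExpressionStudy:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    if "__group__" not in frame.index:
        raise ValueError(f"{path}: missing the __group__ label row")
    labels = [str(v) for v in frame.loc["__group__"]]
    data = frame.drop(index="__group__").astype(float)
    return ExpressionStudy(
        gene_ids=[str(g) for g in data.index],
        matrix=data.to_numpy(),
        group_labels=labels,
    )


def write_gene_list(path: str | Path, genes: Sequence[str]) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in genes))


def read_gene_list(path: str | Path) -> list[str]:
    return [
        line.strip()
        for line in Path(path).read_text().splitlines()
        if line.strip() and not line.startswith("#")
    ]
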