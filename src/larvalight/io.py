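"""File formats: TIFF stacks with spacing metadata, CSV tables, profile
libraries, and readers for the plain-text per-fish table dialects.

All writes are atomic (temp file in the target directory, then rename), so
a crashed run never leaves a truncated output behind.
"""

from __future__ import annotations

import csv
import json
import os
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .cohort import FishRecord
from .grids import DataError, ValidationError, VoxelGrid
from .positioning import IntensityProfile, TemplateLibrary
from .segmentation import NeutrophilObject

SPACING_KEY = "spacing_um_zyx"


def atomic_write(path: str | Path, writer) -> None:
    """Call ``writer(temp_path)`` then atomically rename onto ``path``."""
    path = Path(path)
    fd, tmp = tempfile.mkstemp(dir=path.parent or Path("."), suffix=path.suffix)
    os.close(fd)
    try:
        writer(tmp)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_stack(grid: VoxelGrid, path: str | Path) -> None:
    """Write a multi-page TIFF; voxel spacing goes in the ImageDescription
    (JSON) and the in-plane pitch additionally in the resolution tags."""
    dz, dy, dx = grid.spacing
    desc = json.dumps({SPACING_KEY: [dz, dy, dx]})

    def _write(tmp: str) -> None:
        tifffile.imwrite(
            tmp,
            grid.data,
            photometric="minisblack",
            description=desc,
            resolution=(1.0 / dx, 1.0 / dy),
        )

    atomic_write(path, _write)


def read_stack(path: str | Path, spacing_override: tuple[float, float, float] | None = None) -> VoxelGrid:
    """Read a multi-page TIFF into a (z, y, x) grid.

    Spacing comes from the JSON ImageDescription written by
    :func:`write_stack`, else from ImageJ-style metadata, else from
    ``spacing_override``.  Missing everywhere is an error — never a silent
    default.
    """
    path = Path(path)
    try:
        with tifffile.TiffFile(path) as tif:
            data = tif.asarray()
            spacing = _spacing_from_tiff(tif)
    except (tifffile.TiffFileError, FileNotFoundError, ValueError) as exc:
        raise DataError(f"cannot read TIFF stack {path}: {exc}") from exc
    if data.ndim == 2:
        data = data[None, :, :]
    if data.ndim != 3:
        raise DataError(f"{path} holds a {data.ndim}D array; expected a 3D stack")
    if spacing is None:
        spacing = spacing_override
    if spacing is None:
        raise DataError(
            f"{path} carries no voxel-spacing metadata and no override was given; "
            "pass spacing explicitly"
        )
    return VoxelGrid(data, spacing)


def _spacing_from_tiff(tif: tifffile.TiffFile) -> tuple[float, float, float] | None:
    page = tif.pages[0]
    desc = page.description or ""
    try:
        meta = json.loads(desc)
        if isinstance(meta, dict) and SPACING_KEY in meta:
            dz, dy, dx = (float(v) for v in meta[SPACING_KEY])
            return (dz, dy, dx)
    except (json.JSONDecodeError, TypeError, ValueError):
        pass
    if tif.imagej_metadata:
        dz = tif.imagej_metadata.get("spacing")
        tags = page.tags
        if dz and "XResolution" in tags and "YResolution" in tags:
            xr = tags["XResolution"].value
            yr = tags["YResolution"].value
            dx = xr[1] / xr[0]
            dy = yr[1] / yr[0]
            return (float(dz), float(dy), float(dx))
    return None


def write_labels(labels: np.ndarray, spacing: tuple[float, float, float], path: str | Path) -> None:
    """Write a labeled volume as 16-bit TIFF (labels above 65535 rejected)."""
    if labels.max() > np.iinfo(np.uint16).max:
        raise ValidationError("more than 65535 labels cannot be stored as 16-bit TIFF")
    write_stack(VoxelGrid(labels.astype(np.uint16), spacing), path)


def write_objects_csv(objects: list[NeutrophilObject], path: str | Path) -> None:
    rows = [
        {
            "label": o.label,
            "x_um": o.centroid[0],
            "y_um": o.centroid[1],
            "z_um": o.centroid[2],
            "voxels": o.voxel_count,
            "volume_um3": o.volume,
            "total_intensity": o.total_intensity,
        }
        for o in objects
    ]
    df = pd.DataFrame(rows, columns=["label", "x_um", "y_um", "z_um", "voxels", "volume_um3", "total_intensity"])
    atomic_write(path, lambda tmp: df.to_csv(tmp, index=False))


def write_ground_truth_csv(blobs, path: str | Path) -> None:
    rows = [
        {
            "x_um": b.center[0],
            "y_um": b.center[1],
            "z_um": b.center[2],
            "rx": b.radii[0],
            "ry": b.radii[1],
            "rz": b.radii[2],
            "peak": b.peak_intensity,
        }
        for b in blobs
    ]
    df = pd.DataFrame(rows, columns=["x_um", "y_um", "z_um", "rx", "ry", "rz", "peak"])
    atomic_write(path, lambda tmp: df.to_csv(tmp, index=False))


def write_profile_csv(profile: IntensityProfile, path: str | Path) -> None:
    df = pd.DataFrame({"position_um": profile.positions, "intensity": profile.values})
    atomic_write(path, lambda tmp: df.to_csv(tmp, index=False))


def read_profile_csv(path: str | Path) -> IntensityProfile:
    df = pd.read_csv(path)
    if not {"position_um", "intensity"}.issubset(df.columns):
        raise DataError(f"{path} is not a profile CSV (needs position_um,intensity)")
    pos = df["position_um"].to_numpy(dtype=float)
    if pos.size < 2:
        raise DataError(f"{path} has fewer than 2 samples")
    steps = np.diff(pos)
    if not np.allclose(steps, steps[0]):
        raise DataError(f"{path} is not uniformly sampled")
    return IntensityProfile(df["intensity"].to_numpy(dtype=float), float(steps[0]), float(pos[0]))


def save_library(library: TemplateLibrary, directory: str | Path) -> None:
    """Store a template library as one CSV per template plus a manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {}
    for name, profile in library.templates:
        fname = f"{name}.csv"
        write_profile_csv(profile, directory / fname)
        manifest[name] = fname
    atomic_write(
        directory / "manifest.yaml",
        lambda tmp: Path(tmp).write_text(yaml.safe_dump({"templates": manifest})),
    )


def load_library(directory: str | Path) -> TemplateLibrary:
    directory = Path(directory)
    manifest_path = directory / "manifest.yaml"
    if not manifest_path.exists():
        raise DataError(f"no manifest.yaml in library directory {directory}")
    manifest = yaml.safe_load(manifest_path.read_text())
    templates = []
    for name, fname in manifest.get("templates", {}).items():
        templates.append((name, read_profile_csv(directory / fname)))
    return TemplateLibrary(templates)


def read_values_table(path: str | Path) -> list[float]:
    """One numeric value per line (the counts / intensities / positions
    dialect of per-fish text tables); blank lines ignored."""
    path = Path(path)
    values: list[float] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            try:
                values.append(float(line))
            except ValueError as exc:
                raise DataError(f"{path}:{lineno}: non-numeric value {line!r}") from exc
    if not values:
        raise DataError(f"{path} holds no values")
    return values


def read_fish_table(
    path: str | Path,
    dialect: str = "one-per-line",
    intensities_path: str | Path | None = None,
) -> list[FishRecord]:
    """Read per-fish records from the supplementary-style plain-text dialects.

    "one-per-line": one count per line; an optional second file supplies the
    total intensities in the same fish order (lengths must match).
    "labeled-csv": delimited text with labeled rows — either wide rows
    (``label, v1, v2, ...``: one row per group, one value per fish) or a
    two-column long layout (``group, count`` with an optional header).  The
    delimiter is sniffed.
    """
    if dialect == "one-per-line":
        counts = read_values_table(path)
        intensities: list[float] | None = None
        if intensities_path is not None:
            intensities = read_values_table(intensities_path)
            if len(intensities) != len(counts):
                raise DataError(
                    f"paired tables disagree in length: {len(counts)} counts vs "
                    f"{len(intensities)} intensities"
                )
        return [
            FishRecord(
                fish_id=f"fish{i:03d}",
                count=c,
                total_intensity=intensities[i] if intensities else None,
            )
            for i, c in enumerate(counts)
        ]
    if dialect == "labeled-csv":
        return _read_labeled_csv(path)
    raise ValidationError(f"unknown table dialect {dialect!r}")


def _is_number(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


def _read_labeled_csv(path: str | Path) -> list[FishRecord]:
    path = Path(path)
    text = path.read_text()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise DataError(f"{path} is empty")
    try:
        delim = csv.Sniffer().sniff(lines[0], delimiters=",;\t ").delimiter
    except csv.Error:
        delim = ","
    rows = [[tok.strip() for tok in ln.split(delim) if tok.strip() != ""] for ln in lines]
    # two-column long layout? (group, count) per row, optional header
    if all(len(r) == 2 for r in rows) and any(_is_number(r[1]) for r in rows):
        start = 0 if _is_number(rows[0][1]) else 1  # skip a header line
        records = []
        for i, (group, val) in enumerate(rows[start:], start=start + 1):
            if not _is_number(val):
                raise DataError(f"{path}:{i}: non-numeric count {val!r}")
            records.append(FishRecord(fish_id=f"fish{i - start - 1:03d}", count=float(val), group=group))
        return records
    # wide layout: label, v1, v2, ...
    records = []
    fish_idx = 0
    for i, row in enumerate(rows, start=1):
        if len(row) < 2 or _is_number(row[0]):
            raise DataError(f"{path}:{i}: expected 'label, v1, v2, ...'")
        group = row[0]
        for tok in row[1:]:
            if not _is_number(tok):
                raise DataError(f"{path}:{i}: non-numeric count {tok!r}")
            records.append(FishRecord(fish_id=f"fish{fish_idx:03d}", count=float(tok), group=group))
            fish_idx += 1
    return records


def write_fish_table(records: list[FishRecord], path: str | Path, dialect: str = "one-per-line") -> None:
    """Write per-fish records in a supplementary-style dialect."""
    if dialect == "one-per-line":
        body = "\n".join(str(r.count) for r in records) + "\n"
        atomic_write(path, lambda tmp: Path(tmp).write_text(body))
        return
    if dialect == "labeled-csv":
        groups: dict[str, list[float]] = {}
        for r in records:
            groups.setdefault(r.group or "all", []).append(r.count)
        body = "\n".join(g + "," + ",".join(str(v) for v in vals) for g, vals in groups.items()) + "\n"
        atomic_write(path, lambda tmp: Path(tmp).write_text(body))
        return
    raise ValidationError(f"unknown table dialect {dialect!r}")


def write_json_report(report: dict, path: str | Path) -> None:
    atomic_write(path, lambda tmp: Path(tmp).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n"))
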