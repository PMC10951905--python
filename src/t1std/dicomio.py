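"""DICOM / mask input and tabular result output.

T1 maps arrive as single-frame DICOM files whose stored pixel values are
rescaled to ms via the rescale slope/intercept (defaulting to 1/0 when
absent, as common DICOM practice). Masks are lossless single-channel
rasters (PNG) on exactly the same grid — nonzero means myocardium, no
resampling ever happens.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .confounders import extract_cp_vector
from .errors import ExtractionError, InputError
from .model import StandardisationResult
from .records import T1MapRecord

logger = logging.getLogger("t1std")


def read_t1_map(dicom_path) -> T1MapRecord:
    """Read one single-frame T1-map DICOM into a record (mask and cohort
    are attached separately).

    Pixel values become ``stored * RescaleSlope + RescaleIntercept`` in ms.
    ``source_meta`` retains all non-pixel attributes keyed by lowercase hex
    tag ``"gggg,eeee"`` (multi-value attributes as lists) for CP extraction
    and traceability.
    """
    import pydicom

    path = Path(dicom_path)
    try:
        ds = pydicom.dcmread(path)
    except Exception as exc:
        raise InputError(f"unreadable DICOM file {path}: {exc}") from None
    if "PixelData" not in ds:
        raise InputError(f"DICOM file {path} lacks pixel data")
    try:
        stored = ds.pixel_array
    except Exception as exc:
        raise InputError(f"cannot decode pixel data of {path}: {exc}") from None
    if stored.ndim != 2:
        raise InputError(
            f"DICOM file {path} has {stored.ndim}-D pixel data; expected 2-D"
        )
    slope = float(getattr(ds, "RescaleSlope", 1.0))
    intercept = float(getattr(ds, "RescaleIntercept", 0.0))
    pixels = stored.astype(np.float64) * slope + intercept

    source_meta: dict = {}
    for elem in ds:
        if elem.tag.group == 0x7FE0:  # pixel data
            continue
        key = f"{elem.tag.group:04x},{elem.tag.element:04x}"
        if elem.VM > 1:
            source_meta[key] = [str(v) for v in elem.value]
        else:
            source_meta[key] = str(elem.value)

    map_id = str(getattr(ds, "SOPInstanceUID", "")) or path.stem
    return T1MapRecord(
        map_id=map_id,
        subject_id=str(getattr(ds, "PatientID", "")),
        pixels=pixels,
        source_meta=source_meta,
    )


def read_mask(mask_path, target_shape) -> np.ndarray:
    """Read a lossless single-channel raster mask; nonzero -> 1."""
    from PIL import Image

    path = Path(mask_path)
    try:
        img = Image.open(path)
        arr = np.asarray(img)
    except Exception as exc:
        raise InputError(f"unreadable mask file {path}: {exc}") from None
    if arr.ndim != 2:
        raise InputError(
            f"mask {path} is not single-channel (shape {arr.shape})"
        )
    if arr.shape != tuple(target_shape):
        raise InputError(
            f"mask shape {arr.shape} does not match T1-map shape "
            f"{tuple(target_shape)}"
        )
    return (arr != 0).astype(np.uint8)


def load_dataset(data_dir, cps, cohort_filter: str | None = None,
                 strict: bool = False) -> list[T1MapRecord]:
    """Load a directory written by :func:`t1std.synthetic.write_cohort` (or
    hand-assembled in the same layout): DICOMs + PNG masks indexed by
    ``labels.csv`` with columns dicom, mask, map_id, subject_id, cohort.

    Records failing CP extraction are excluded with a logged warning; in
    strict mode they abort the batch.
    """
    data_dir = Path(data_dir)
    index_path = data_dir / "labels.csv"
    if not index_path.exists():
        raise InputError(f"no labels.csv index in {data_dir}")
    index = pd.read_csv(index_path)
    records = []
    for row in index.itertuples(index=False):
        if cohort_filter is not None and str(row.cohort) != cohort_filter:
            continue
        rec = read_t1_map(data_dir / row.dicom)
        rec.map_id = str(row.map_id)
        rec.subject_id = str(row.subject_id)
        rec.cohort = str(row.cohort)
        rec.mask = read_mask(data_dir / row.mask, rec.pixels.shape)
        try:
            rec.cp_values = extract_cp_vector(rec, cps)
        except ExtractionError as exc:
            if strict:
                raise
            logger.warning("excluding map %s: %s", rec.map_id, exc)
            continue
        rec.validate()
        records.append(rec)
    return records


def write_result_table(results: list[StandardisationResult], out_path):
    """One row per map: CP values, mean before, per-CP mean bias
    components, mean after. Writes CSV or XLSX depending on the suffix."""
    if not results:
        raise InputError("no standardisation results to write")
    rows = []
    for r in results:
        row = {
            "map_id": r.map_id,
            "subject_id": r.subject_id,
            "cohort": r.cohort,
        }
        row.update({f"cp_{k}": v for k, v in r.cp_values.items()})
        row["mean_before"] = r.mean_before
        for name, comp in r.bias_components:
            row[f"bias_{name}"] = float(np.mean(comp))
        row["mean_after"] = r.mean_after
        rows.append(row)
    frame = pd.DataFrame(rows)
    out_path = Path(out_path)
    try:
        if out_path.suffix.lower() in (".xlsx", ".xls"):
            frame.to_excel(out_path, index=False)
        else:
            frame.to_csv(out_path, index=False)
    except OSError as exc:
        raise InputError(f"cannot write result table {out_path}: {exc}") from None
    return frame


def write_result_container(results: list[StandardisationResult], out_path):
    """Machine-readable per-pixel result container (JSON).

    Key set per entry: map_id, cp_values, values_original, bias_components
    (ordered by CP), values_standardised. Round-trips exactly: floats are
    serialised via repr-faithful JSON."""
    if not results:
        raise InputError("no standardisation results to write")
    payload = {
        "format": "t1std-results",
        "format_version": 1,
        "results": [r.to_dict() for r in results],
    }
    out_path = Path(out_path)
    try:
        with open(out_path, "w") as fh:
            json.dump(payload, fh)
    except OSError as exc:
        raise InputError(
            f"cannot write result container {out_path}: {exc}"
        ) from None
    return out_path


def read_result_container(path) -> list[StandardisationResult]:
    path = Path(path)
    try:
        with open(path) as fh:
            payload = json.load(fh)
    except (OSError, json.JSONDecodeError) as exc:
        raise InputError(f"unreadable result container {path}: {exc}") from None
    if payload.get("format") != "t1std-results":
        raise InputError(f"{path} is not a t1std result container")
    return [StandardisationResult.from_dict(d) for d in payload["results"]]
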