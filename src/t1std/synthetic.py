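"""Synthetic T1-map cohorts with known confounder effects.

Generates ring-phantom maps (an annulus mimics the full circular
mid-ventricular myocardium segmentation) whose values carry injected,
exactly known CP biases — age slope, additive/multiplicative category
effects, disease offsets — plus per-pixel Gaussian noise. Every pipeline
stage is thereby testable without clinical data, and the returned
ground-truth table provides the oracle for recovery tests.

The default healthy design is "anchored": a reference-environment block,
one block per CP varying only that CP (emulating the controlled
sub-studies found in pooled multi-centre healthy collections — these make
the individual and cascaded modes trainable), and a fully mixed remainder.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .confounders import ConfounderDef, default_cp_definitions
from .errors import ConfigurationError, InputError
from .records import T1MapRecord

#: Plausible baseline myocardial native T1 at the 3.0 T reference setup.
DEFAULT_BASE_MEAN = 1150.0   # ms
DEFAULT_BASE_SD = 40.0       # ms, between-subject
DEFAULT_PIXEL_NOISE = 30.0   # ms, within-map

_SEQUENCE_DESCRIPTIONS = {
    "MOLLI533b": "T1 Map MOLLI 5(3)3 b",
    "MOLLI335b": "T1 Map MOLLI 3(3)5 b",
    "SASHA": "T1 Map SASHA GRE",
}


@dataclass
class EffectSpec:
    """Injected CP effects.

    ``categorical`` maps CP name -> category -> ``(kind, value)`` with kind
    ``"additive"`` (ms) or ``"multiplicative"`` (factor > 0); reference
    categories carry zero effect and need no entry. ``age_slope`` is in
    ms/year relative to the reference age. ``disease_offsets`` are additive
    ms per cohort label; magnitudes default to roughly +50 ms (HCM) and
    +200 ms (AMY) over healthy, in line with published standardised cohort
    separations.
    """

    categorical: dict = field(default_factory=dict)
    age_slope: float = 0.0
    disease_offsets: dict = field(default_factory=dict)

    def validate(self, categories: dict) -> None:
        for cp_name, per_cat in self.categorical.items():
            if cp_name not in categories:
                raise ConfigurationError(
                    f"effect references unknown CP {cp_name!r}"
                )
            for cat, (kind, value) in per_cat.items():
                if cat not in categories[cp_name]:
                    raise ConfigurationError(
                        f"effect references unknown category {cat!r} "
                        f"of CP {cp_name!r}"
                    )
                if kind not in ("additive", "multiplicative"):
                    raise ConfigurationError(f"unknown effect kind {kind!r}")
                if kind == "multiplicative" and value <= 0:
                    raise ConfigurationError(
                        f"multiplicative factor must be > 0, got {value}"
                    )


def default_effects() -> EffectSpec:
    """Defaults emulating the dominant published confounder magnitudes:
    field strength is the largest technical effect (a 1.5 T scanner reads
    ~150 ms lower than 3.0 T), sequence variants differ by tens of ms, sex
    and age effects are small."""
    return EffectSpec(
        categorical={
            "sex": {"female": ("additive", 20.0)},
            "scanner": {"1.5T-GEN": ("additive", -150.0)},
            "sequence": {"MOLLI335b": ("additive", -30.0)},
        },
        age_slope=0.8,
        disease_offsets={"healthy": 0.0, "HCM": 50.0, "AMY": 200.0},
    )


def default_categories() -> dict:
    return {
        "sex": ["male", "female"],
        "scanner": ["3.0T-REF", "1.5T-GEN"],
        "sequence": ["MOLLI533b", "MOLLI335b"],
    }


def render_ring_phantom(image_size: int, r_outer: float, r_inner: float,
                        value: float) -> tuple[np.ndarray, np.ndarray]:
    """Annulus phantom: mask of lattice points with r_inner <= d <= r_outer
    from the image centre; pixels hold ``value`` inside, 0 outside."""
    if not (0 < r_inner < r_outer < image_size / 2):
        raise ConfigurationError(
            f"need 0 < r_inner < r_outer < image_size/2, got "
            f"{r_inner}, {r_outer}, {image_size}"
        )
    c = (image_size - 1) / 2.0
    yy, xx = np.mgrid[0:image_size, 0:image_size]
    d = np.sqrt((yy - c) ** 2 + (xx - c) ** 2)
    mask = ((d >= r_inner) & (d <= r_outer)).astype(np.uint8)
    pixels = np.where(mask > 0, float(value), 0.0)
    return pixels, mask


def _design_roles(n_subjects: int, block_cps: list[str], design: str):
    if design == "mixed" or not block_cps:
        return ["mixed"] * n_subjects
    roles: list = ["ref"] * max(2, int(round(0.2 * n_subjects)))
    n_blocks = max(len(block_cps), int(round(0.5 * n_subjects)))
    roles += [("vary", block_cps[i % len(block_cps)]) for i in range(n_blocks)]
    roles += ["mixed"] * n_subjects
    return roles[:n_subjects]


def generate_cohort(
    n_subjects: int,
    cps: list[ConfounderDef] | None = None,
    effects: EffectSpec | None = None,
    categories: dict | None = None,
    base_mean: float = DEFAULT_BASE_MEAN,
    base_sd: float = DEFAULT_BASE_SD,
    noise_pixel_sd: float = DEFAULT_PIXEL_NOISE,
    maps_per_subject: int = 1,
    cohort: str = "healthy",
    seed: int = 0,
    image_size: int = 32,
    r_outer: float = 10.0,
    r_inner: float = 6.0,
    design: str | None = None,
    vary_across_maps: str | None = None,
    id_prefix: str = "",
) -> tuple[list[T1MapRecord], pd.DataFrame]:
    """Generate ``n_subjects`` subjects with known injected biases.

    Returns the records plus a ground-truth table holding, per map, the CP
    values, subject base T1, each injected bias component and the clean
    (noise-free) myocardial value.

    Per map the clean value is built as base, plus the age slope, times
    any multiplicative category factors, plus additive category offsets,
    plus the cohort's disease offset; pixel noise is then added inside the
    rendered ring mask. ``design`` is ``"anchored"`` (default for healthy)
    or ``"mixed"`` (default otherwise); with ``maps_per_subject > 1`` the
    ``vary_across_maps`` CP (default: scanner, if configured) cycles its
    categories across a subject's maps, emulating intra-subject rescans in
    different CP environments.
    """
    if n_subjects < 1:
        raise ConfigurationError("n_subjects must be >= 1")
    cps = list(cps) if cps is not None else default_cp_definitions()
    by_name = {cp.name: cp for cp in cps}
    cat_names = [cp.name for cp in cps if cp.representation == "categorical"]
    num_names = [cp.name for cp in cps if cp.representation == "numerical"]
    if len(num_names) > 1:
        raise ConfigurationError(
            "the generator supports at most one numerical CP (age)"
        )
    age_name = num_names[0] if num_names else None
    ref_age = float(by_name[age_name].reference_value) if age_name else None

    if categories is None:
        categories = {
            k: v for k, v in default_categories().items() if k in cat_names
        }
    for name in cat_names:
        cats = categories.get(name)
        if not cats:
            raise ConfigurationError(f"CP {name!r} has no categories")
        ref = str(by_name[name].reference_value)
        if ref not in cats:
            raise ConfigurationError(
                f"reference category {ref!r} missing from CP {name!r}"
            )
    effects = effects if effects is not None else default_effects()
    effects.validate(categories)

    if design is None:
        design = "anchored" if cohort == "healthy" else "mixed"
    if vary_across_maps is None and maps_per_subject > 1:
        vary_across_maps = "scanner" if "scanner" in cat_names else (
            cat_names[0] if cat_names else None
        )
    if vary_across_maps is not None and vary_across_maps not in cat_names:
        raise ConfigurationError(
            f"vary_across_maps CP {vary_across_maps!r} is not categorical"
        )

    rng = np.random.default_rng(seed)
    block_cps = cat_names + ([age_name] if age_name else [])
    roles = _design_roles(n_subjects, block_cps, design)
    vary_counters = {name: 0 for name in block_cps}
    disease_offset = float(effects.disease_offsets.get(cohort, 0.0))

    records: list[T1MapRecord] = []
    truth_rows: list[dict] = []

    for s_idx in range(n_subjects):
        subject_id = f"{id_prefix}{cohort}-{s_idx:03d}"
        base = float(rng.normal(base_mean, base_sd))
        role = roles[s_idx]

        cp_subject: dict = {}
        if role == "ref":
            for name in cat_names:
                cp_subject[name] = str(by_name[name].reference_value)
            if age_name:
                cp_subject[age_name] = ref_age
        elif isinstance(role, tuple):
            _, vary_cp = role
            for name in cat_names:
                cp_subject[name] = str(by_name[name].reference_value)
            if age_name:
                cp_subject[age_name] = ref_age
            if vary_cp == age_name:
                cp_subject[age_name] = float(rng.integers(18, 81))
            else:
                cats = categories[vary_cp]
                # reference block already covers the reference category;
                # start the cycle at the first non-reference one
                cp_subject[vary_cp] = cats[(1 + vary_counters[vary_cp])
                                           % len(cats)]
                vary_counters[vary_cp] += 1
        else:  # mixed
            for name in cat_names:
                cp_subject[name] = str(rng.choice(categories[name]))
            if age_name:
                cp_subject[age_name] = float(rng.integers(18, 81))

        for m_idx in range(maps_per_subject):
            cp_values = dict(cp_subject)
            if vary_across_maps is not None and maps_per_subject > 1:
                cats = categories[vary_across_maps]
                cp_values[vary_across_maps] = cats[m_idx % len(cats)]

            value = base
            bias: dict[str, float] = {}
            if age_name:
                delta = effects.age_slope * (cp_values[age_name] - ref_age)
                bias[age_name] = delta
                value += delta
            # multiplicative category effects precede additive ones
            for kind_pass in ("multiplicative", "additive"):
                for name in cat_names:
                    eff = effects.categorical.get(name, {}).get(
                        cp_values[name]
                    )
                    if eff is None:
                        bias.setdefault(name, 0.0)
                        continue
                    kind, magnitude = eff
                    if kind != kind_pass:
                        continue
                    if kind == "multiplicative":
                        bias[name] = value * (magnitude - 1.0)
                        value *= magnitude
                    else:
                        bias[name] = magnitude
                        value += magnitude
            value += disease_offset

            pixels, mask = render_ring_phantom(image_size, r_outer, r_inner,
                                               value)
            if noise_pixel_sd > 0:
                noise = rng.normal(0.0, noise_pixel_sd, size=pixels.shape)
                pixels = pixels + noise * mask
            map_id = f"{subject_id}-{m_idx:02d}"

            source_meta = {
                "0008,103e": _SEQUENCE_DESCRIPTIONS.get(
                    cp_values.get("sequence", ""),
                    str(cp_values.get("sequence", "")),
                ),
            }
            if age_name:
                source_meta["0010,1010"] = f"{int(cp_values[age_name]):03d}Y"
            if "sex" in cp_values:
                source_meta["0010,0040"] = (
                    "M" if cp_values["sex"] == "male" else "F"
                )
            if "scanner" in cp_values:
                source_meta["0008,1090"] = cp_values["scanner"]

            rec = T1MapRecord(
                map_id=map_id,
                subject_id=subject_id,
                cohort=cohort,
                pixels=pixels,
                mask=mask,
                cp_values=cp_values,
                source_meta=source_meta,
            )
            rec.validate()
            records.append(rec)

            row = {
                "map_id": map_id,
                "subject_id": subject_id,
                "cohort": cohort,
                "base_t1": base,
                "clean_value": value,
                "disease_offset": disease_offset,
            }
            row.update({f"cp_{k}": v for k, v in cp_values.items()})
            row.update({f"bias_{k}": v for k, v in bias.items()})
            row["bias_total"] = value - base
            truth_rows.append(row)

    return records, pd.DataFrame(truth_rows)


def write_cohort(records, out_dir, ground_truth: pd.DataFrame | None = None):
    """Write records as DICOM files + PNG masks + a labels.csv index (and
    the ground-truth table, if given) so the IO layer can be exercised
    end-to-end. Pixel values are stored with rescale slope 0.1 (0.1 ms
    resolution)."""
    import pydicom
    from pydicom.dataset import FileDataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, MRImageStorage
    from PIL import Image
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, rec in enumerate(records):
        rec.validate()
        stem = rec.map_id.replace("/", "_")
        dcm_name, png_name = f"{stem}.dcm", f"{stem}_mask.png"

        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = MRImageStorage
        meta.MediaStorageSOPInstanceUID = f"1.2.826.0.1.3680043.8.498.{i + 1}"
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds = FileDataset(dcm_name, {}, file_meta=meta, preamble=b"\0" * 128)
        ds.SOPClassUID = MRImageStorage
        ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
        ds.Modality = "MR"
        ds.PatientID = rec.subject_id
        ds.StudyDescription = rec.cohort
        if "0010,1010" in rec.source_meta:
            ds.PatientAge = rec.source_meta["0010,1010"]
        if "0010,0040" in rec.source_meta:
            ds.PatientSex = rec.source_meta["0010,0040"]
        if "0008,1090" in rec.source_meta:
            ds.ManufacturerModelName = rec.source_meta["0008,1090"]
        if "0008,103e" in rec.source_meta:
            ds.SeriesDescription = rec.source_meta["0008,103e"]

        arr = np.round(rec.pixels / 0.1).astype(np.uint16)
        ds.Rows, ds.Columns = arr.shape
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0
        ds.RescaleSlope = "0.1"
        ds.RescaleIntercept = "0"
        ds.PixelData = arr.tobytes()
        ds.save_as(out / dcm_name, enforce_file_format=True)

        Image.fromarray((rec.mask > 0).astype(np.uint8) * 255).save(
            out / png_name
        )
        rows.append({
            "dicom": dcm_name, "mask": png_name, "map_id": rec.map_id,
            "subject_id": rec.subject_id, "cohort": rec.cohort,
        })
    pd.DataFrame(rows).to_csv(out / "labels.csv", index=False)
    if ground_truth is not None:
        ground_truth.to_csv(out / "ground_truth.csv", index=False)
    return out
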