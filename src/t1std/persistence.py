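"""Pipeline archives: self-contained, versioned, traceable.

A trained pipeline is stored as a single zip archive holding a JSON
manifest (setting, CP definitions with reference values, bin partition,
per-bin targets, category codebooks, optional training fingerprint, and —
for linear models — the portable coefficients) plus the pickled
scikit-learn estimators, with the exact library version recorded for the
opaque part. Archives standardise identically across sessions and do not
depend on the training data files; exporting without the fingerprint drops
traceability but keeps full functionality.
"""

from __future__ import annotations

import io
import json
import pickle
import zipfile
from datetime import datetime, timezone
from pathlib import Path

import numpy as np

from .confounders import ConfounderDef
from .binning import BinPartition
from .errors import ArchiveError, InputError
from .model import FittedPipeline, PipelineSetting

FORMAT_VERSION = 1
_MANIFEST = "manifest.json"
_MODELS = "models.pkl"


def _linear_summaries(submodels) -> dict:
    """Portable coefficient dump for any fitted linear estimators found in
    the submodel tree (informational; loading uses the pickle)."""
    out = {}

    def walk(obj, path):
        if isinstance(obj, dict):
            for k, v in obj.items():
                walk(v, f"{path}/{k}")
        elif hasattr(obj, "coef_"):
            out[path] = {
                "coef": np.atleast_1d(obj.coef_).tolist(),
                "intercept": float(np.atleast_1d(obj.intercept_)[0]),
            }

    walk(submodels, "")
    return out


def save_pipeline(model: FittedPipeline, path,
                  include_fingerprint: bool = True) -> Path:
    """Write a fitted pipeline to a single archive file."""
    if not isinstance(model, FittedPipeline) or model.submodels is None:
        raise InputError("save_pipeline requires a fitted pipeline")
    import sklearn

    manifest = {
        "format": "t1std-pipeline",
        "format_version": FORMAT_VERSION,
        "created": datetime.now(timezone.utc).isoformat(),
        "sklearn_version": sklearn.__version__,
        "setting": model.setting.to_dict(),
        "cps": [cp.to_dict() for cp in model.cps],
        "partition": model.partition.to_dict(),
        "per_bin_targets": model.per_bin_targets.tolist(),
        "category_codebooks": model.category_codebooks,
        "uncovered": [list(u) for u in model.uncovered],
        "linear_coefficients": _linear_summaries(model.submodels),
    }
    if include_fingerprint:
        manifest["training_fingerprint"] = model.training_fingerprint

    path = Path(path)
    try:
        with zipfile.ZipFile(path, "w", zipfile.ZIP_DEFLATED) as zf:
            zf.writestr(_MANIFEST, json.dumps(manifest, indent=2))
            buf = io.BytesIO()
            pickle.dump(model.submodels, buf, protocol=4)
            zf.writestr(_MODELS, buf.getvalue())
    except OSError as exc:
        raise InputError(f"cannot write pipeline archive {path}: {exc}") from None
    return path


def load_pipeline(path) -> FittedPipeline:
    """Restore a pipeline archive; output-identical to the saved model."""
    path = Path(path)
    try:
        with zipfile.ZipFile(path) as zf:
            manifest = json.loads(zf.read(_MANIFEST))
            models_blob = zf.read(_MODELS)
    except (OSError, zipfile.BadZipFile, KeyError) as exc:
        raise ArchiveError(f"corrupt or unreadable archive {path}: {exc}") from None
    except json.JSONDecodeError as exc:
        raise ArchiveError(f"corrupt manifest in {path}: {exc}") from None

    if manifest.get("format") != "t1std-pipeline":
        raise ArchiveError(f"{path} is not a t1std pipeline archive")
    version = manifest.get("format_version")
    if version != FORMAT_VERSION:
        raise ArchiveError(
            f"unsupported archive format version {version!r} "
            f"(this build reads version {FORMAT_VERSION})"
        )

    submodels = pickle.loads(models_blob)
    return FittedPipeline(
        setting=PipelineSetting.from_dict(manifest["setting"]),
        cps=[ConfounderDef.from_dict(d) for d in manifest["cps"]],
        partition=BinPartition.from_dict(manifest["partition"]),
        per_bin_targets=np.asarray(manifest["per_bin_targets"],
                                   dtype=np.float64),
        submodels=submodels,
        category_codebooks={
            k: {c: int(i) for c, i in v.items()}
            for k, v in manifest.get("category_codebooks", {}).items()
        },
        training_fingerprint=manifest.get("training_fingerprint", {}),
        uncovered=[tuple(u) for u in manifest.get("uncovered", [])],
    )
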