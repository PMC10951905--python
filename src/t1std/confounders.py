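"""Confounding-parameter (CP) definitions and metadata extraction.

A CP is any subject-specific (age, sex) or technical (scanner, sequence
variant) factor that biases apparent T1 values. Each CP is defined by where
it lives in the DICOM metadata, whether it is numerical or categorical, and
its reference value — the value assumed bias-free, into whose environment
all maps are transformed.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .errors import ExtractionError

__all__ = [
    "ConfounderDef",
    "parse_age",
    "parse_sequence_variant",
    "extract_cp_vector",
    "default_cp_definitions",
]

#: DICOM tag of the series description, used by the derived sequence extractor.
_SERIES_DESCRIPTION_TAG = "0008,103e"

_TAG_RE = re.compile(r"^\(?([0-9a-fA-F]{4})\s*,\s*([0-9a-fA-F]{4})\)?(?:\[(\d+)\])?$")


@dataclass(frozen=True)
class ConfounderDef:
    """Definition of one confounding parameter.

    Parameters
    ----------
    name
        Unique identifier within a CP set (e.g. ``"age"``).
    source
        Either a DICOM tag path ``"GGGG,EEEE"`` (hex), optionally with a
        value index ``"GGGG,EEEE[i]"`` for multi-value tags, or a derived
        extractor id of the form ``"derived:series_description"``.
    representation
        ``"numerical"`` or ``"categorical"``.
    reference_value
        The CP value of the reference environment (finite real for
        numerical CPs, a category label otherwise).
    extractor_rules
        Ordered ``(pattern, label)`` pairs for string-derived CPs; matching
        is case-insensitive regex search, first match wins.
    value_map
        Optional raw-value -> label mapping applied to categorical CPs
        (e.g. DICOM sex code ``"M"`` -> ``"male"``).
    """

    name: str
    source: str
    representation: str
    reference_value: object
    extractor_rules: tuple[tuple[str, str], ...] = ()
    value_map: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        if self.representation not in ("numerical", "categorical"):
            raise ValueError(
                f"representation must be 'numerical' or 'categorical', "
                f"got {self.representation!r}"
            )
        if self.representation == "numerical":
            try:
                ref = float(self.reference_value)
            except (TypeError, ValueError):
                ref = float("nan")
            if not (ref == ref and abs(ref) != float("inf")):
                raise ValueError(
                    f"numerical CP {self.name!r} needs a finite real "
                    f"reference value, got {self.reference_value!r}"
                )
        if not (self.source.startswith("derived:") or _TAG_RE.match(self.source)):
            raise ValueError(f"unparseable CP source {self.source!r}")
        object.__setattr__(
            self, "extractor_rules", tuple(tuple(r) for r in self.extractor_rules)
        )
        object.__setattr__(
            self, "value_map", tuple(tuple(m) for m in self.value_map)
        )

    # -- (de)serialisation -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "source": self.source,
            "representation": self.representation,
            "reference_value": self.reference_value,
            "extractor_rules": [list(r) for r in self.extractor_rules],
            "value_map": [list(m) for m in self.value_map],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ConfounderDef":
        return cls(
            name=d["name"],
            source=d["source"],
            representation=d["representation"],
            reference_value=d["reference_value"],
            extractor_rules=tuple(tuple(r) for r in d.get("extractor_rules", ())),
            value_map=tuple(tuple(m) for m in d.get("value_map", ())),
        )


def parse_age(raw) -> float:
    """Parse a patient age to years.

    Accepts plain numbers and DICOM age strings of the form ``"nnnY"``.
    Month/week/day suffixes are rejected: the method targets adult cohorts
    where sub-year resolution is meaningless.
    """
    if isinstance(raw, (int, float)):
        return float(raw)
    s = str(raw).strip()
    m = re.fullmatch(r"(\d+)\s*([yY])?", s)
    if m:
        return float(m.group(1))
    if re.fullmatch(r"\d+\s*[mMwWdD]", s):
        raise ExtractionError(f"age {raw!r} uses a sub-year unit; expected years")
    try:
        return float(s)
    except ValueError:
        raise ExtractionError(f"unparseable age value {raw!r}") from None


def parse_sequence_variant(series_description: str,
                           rules: tuple[tuple[str, str], ...]) -> str:
    """Map a DICOM series description to a sequence-variant label.

    ``rules`` is an ordered list of ``(pattern, label)``; patterns are
    matched case-insensitively (regex search, so plain substrings work once
    special characters are escaped by the caller); the first match wins.
    """
    if not rules:
        raise ExtractionError("no sequence extractor rules configured")
    text = str(series_description)
    for pattern, label in rules:
        if re.search(pattern, text, flags=re.IGNORECASE):
            return label
    raise ExtractionError(
        f"no sequence rule matched series description {series_description!r}"
    )


def _resolve_source(source: str, source_meta: dict):
    """Fetch the raw value for a tag-path source from ``source_meta``."""
    m = _TAG_RE.match(source)
    if m is None:  # pragma: no cover - guarded by ConfounderDef
        raise ExtractionError(f"bad CP source {source!r}")
    key = f"{m.group(1).lower()},{m.group(2).lower()}"
    if key not in source_meta:
        raise KeyError(key)
    value = source_meta[key]
    if m.group(3) is not None:
        idx = int(m.group(3))
        seq = value if isinstance(value, (list, tuple)) else [value]
        if idx >= len(seq):
            raise ExtractionError(
                f"value index {idx} out of range for multi-value tag {key}"
            )
        return seq[idx]
    if isinstance(value, (list, tuple)):
        raise ExtractionError(
            f"tag {key} is multi-valued; a value index is required"
        )
    return value


def _extract_one(cp: ConfounderDef, source_meta: dict):
    if cp.source.startswith("derived:"):
        extractor = cp.source.split(":", 1)[1]
        if extractor != "series_description":
            raise ExtractionError(f"unknown derived extractor {extractor!r}")
        if _SERIES_DESCRIPTION_TAG not in source_meta:
            raise KeyError(_SERIES_DESCRIPTION_TAG)
        raw = parse_sequence_variant(
            source_meta[_SERIES_DESCRIPTION_TAG], cp.extractor_rules
        )
    else:
        raw = _resolve_source(cp.source, source_meta)

    if cp.representation == "numerical":
        if cp.name == "age" or cp.source == "0010,1010":
            return parse_age(raw)
        try:
            return float(raw)
        except (TypeError, ValueError):
            raise ExtractionError(
                f"CP {cp.name!r}: value {raw!r} is not numeric"
            ) from None
    label = str(raw).strip()
    for raw_value, mapped in cp.value_map:
        if label == raw_value:
            return mapped
    return label


def extract_cp_vector(record, cps) -> dict:
    """Extract the CP value vector for a :class:`~t1std.records.T1MapRecord`.

    Deterministic and independent of CP list order. Raises
    :class:`~t1std.errors.ExtractionError` naming the CP and the map id when
    a source tag is unresolvable or a value unparseable.
    """
    names = [cp.name for cp in cps]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate CP names in {names}")
    values = {}
    for cp in sorted(cps, key=lambda c: c.name):
        try:
            values[cp.name] = _extract_one(cp, record.source_meta)
        except KeyError:
            raise ExtractionError(
                f"CP {cp.name!r} unresolvable for map {record.map_id!r}: "
                f"missing attribute {cp.source!r}"
            ) from None
        except ExtractionError as exc:
            raise ExtractionError(
                f"CP {cp.name!r} on map {record.map_id!r}: {exc}"
            ) from None
    return {name: values[name] for name in names}


def default_cp_definitions() -> list[ConfounderDef]:
    """The four-CP universe used throughout: age, sex, scanner, sequence.

    Reference environment: 18 years, male, the 3.0 T reference scanner and
    the MOLLI 5(3)3 b sequence scheme.
    """
    return [
        ConfounderDef(
            name="age",
            source="0010,1010",
            representation="numerical",
            reference_value=18.0,
        ),
        ConfounderDef(
            name="sex",
            source="0010,0040",
            representation="categorical",
            reference_value="male",
            value_map=(("M", "male"), ("F", "female")),
        ),
        ConfounderDef(
            name="scanner",
            source="0008,1090",
            representation="categorical",
            reference_value="3.0T-REF",
        ),
        ConfounderDef(
            name="sequence",
            source="derived:series_description",
            representation="categorical",
            reference_value="MOLLI533b",
            extractor_rules=(
                (r"molli\s*5\(3\)3", "MOLLI533b"),
                (r"molli\s*3\(3\)5", "MOLLI335b"),
                (r"sasha", "SASHA"),
            ),
        ),
    ]
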