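"""Confounder-bias estimation and map standardisation.

The core model regresses the difference between the *apparent* T1 value of
a pixel (measured in its actual confounding-parameter environment) and the
*target* T1 value (the mean of reference-environment healthy training data)
on the confounding-parameter values. Applying the model estimates the
CP-induced bias of a new map, which is subtracted pixelwise, transforming
the map into the reference CP environment.

Shape follows the statsmodels convention: :class:`T1BiasModel` is built
from data and a :class:`PipelineSetting`; :meth:`T1BiasModel.fit` returns a
:class:`FittedPipeline` results object that carries the fitted submodels,
bin partition, per-bin targets, coverage diagnostics and ``summary()``, and
from which standardisation, persistence and plotting hang.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field

import numpy as np

from .binning import CLUSTER_TYPES, BinPartition, fit_partition
from .confounders import ConfounderDef
from .errors import ApplicationError, ConfigurationError, InputError
from .records import T1MapRecord

logger = logging.getLogger("t1std")

REGRESSION_TYPES = ("linear", "lsvr", "rfr", "etr")
Y_TYPES = ("absolute", "relative")
MODES = ("individual", "cascaded", "ensemble")

#: Tree-ensemble regressors use 1000 estimators; all other hyperparameters
#: stay at the scikit-learn defaults.
N_TREES = 1000

_ENSEMBLE_COMPONENT = "combined"


@dataclass(frozen=True)
class PipelineSetting:
    """One standardisation-pipeline configuration.

    regression_type : {"linear", "lsvr", "rfr", "etr"}
        Ordinary least squares, linear support vector, random-forest or
        extra-trees regression.
    y_type : {"absolute", "relative"}
        Whether the bias is regressed in ms (shifts all pixels equally) or
        as a fraction of the apparent value (weights the shift by T1).
    mode : {"individual", "cascaded", "ensemble"}
        One regression per CP with the others held at reference;
        sequential per-CP fits on progressively standardised data
        (order-dependent); or a single regression over all CPs at once.
    n_bins, cluster_type
        T1-value binning; ``cluster_type`` is ignored when ``n_bins == 1``.
    cp_order
        CP processing order (None = order of the configured CP set). The
        cascaded outcome depends on it, so it is recorded in the model.
    seed
        Seeds the stochastic regressors and clusterings.
    """

    regression_type: str
    y_type: str
    mode: str
    n_bins: int = 1
    cluster_type: str = "equal_distant"
    cp_order: tuple[str, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.regression_type not in REGRESSION_TYPES:
            raise ConfigurationError(
                f"regression_type must be one of {REGRESSION_TYPES}, "
                f"got {self.regression_type!r}"
            )
        if self.y_type not in Y_TYPES:
            raise ConfigurationError(
                f"y_type must be one of {Y_TYPES}, got {self.y_type!r}"
            )
        if self.mode not in MODES:
            raise ConfigurationError(
                f"mode must be one of {MODES}, got {self.mode!r}"
            )
        if self.n_bins < 1:
            raise ConfigurationError(f"n_bins must be >= 1, got {self.n_bins}")
        if self.cluster_type not in CLUSTER_TYPES:
            raise ConfigurationError(
                f"unknown cluster_type {self.cluster_type!r}"
            )
        if self.cp_order is not None:
            object.__setattr__(self, "cp_order", tuple(self.cp_order))

    def label(self) -> str:
        bins = f"{self.n_bins}"
        if self.n_bins > 1:
            bins += f"/{self.cluster_type}"
        return f"{self.regression_type}/{self.y_type}/{self.mode}/bins={bins}"

    def to_dict(self) -> dict:
        return {
            "regression_type": self.regression_type,
            "y_type": self.y_type,
            "mode": self.mode,
            "n_bins": self.n_bins,
            "cluster_type": self.cluster_type,
            "cp_order": list(self.cp_order) if self.cp_order else None,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineSetting":
        return cls(
            regression_type=d["regression_type"],
            y_type=d["y_type"],
            mode=d["mode"],
            n_bins=int(d.get("n_bins", 1)),
            cluster_type=d.get("cluster_type", "equal_distant"),
            cp_order=tuple(d["cp_order"]) if d.get("cp_order") else None,
            seed=int(d.get("seed", 0)),
        )


@dataclass
class StandardisationResult:
    """Per-map outcome: original segmented values, per-CP bias components
    (single combined entry in ensemble mode) and standardised values, all
    in ms and of equal length."""

    map_id: str
    values_original: np.ndarray
    bias_components: list[tuple[str, np.ndarray]]
    values_standardised: np.ndarray
    mean_before: float
    mean_after: float
    cp_values: dict = field(default_factory=dict)
    subject_id: str = ""
    cohort: str = ""

    def to_dict(self) -> dict:
        return {
            "map_id": self.map_id,
            "subject_id": self.subject_id,
            "cohort": self.cohort,
            "cp_values": self.cp_values,
            "values_original": self.values_original.tolist(),
            "bias_components": [
                [name, comp.tolist()] for name, comp in self.bias_components
            ],
            "values_standardised": self.values_standardised.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StandardisationResult":
        orig = np.asarray(d["values_original"], dtype=np.float64)
        std = np.asarray(d["values_standardised"], dtype=np.float64)
        return cls(
            map_id=d["map_id"],
            subject_id=d.get("subject_id", ""),
            cohort=d.get("cohort", ""),
            cp_values=d.get("cp_values", {}),
            values_original=orig,
            bias_components=[
                (name, np.asarray(comp, dtype=np.float64))
                for name, comp in d["bias_components"]
            ],
            values_standardised=std,
            mean_before=float(orig.mean()),
            mean_after=float(std.mean()),
        )


# ---------------------------------------------------------------------------
# regressor construction and the two submodel flavours
# ---------------------------------------------------------------------------

def _make_regressor(setting: PipelineSetting):
    from sklearn.ensemble import ExtraTreesRegressor, RandomForestRegressor
    from sklearn.linear_model import LinearRegression
    from sklearn.svm import LinearSVR

    if setting.regression_type == "linear":
        return LinearRegression()
    if setting.regression_type == "lsvr":
        return LinearSVR(random_state=setting.seed, dual="auto")
    if setting.regression_type == "rfr":
        return RandomForestRegressor(
            n_estimators=N_TREES, random_state=setting.seed, n_jobs=1
        )
    return ExtraTreesRegressor(
        n_estimators=N_TREES, random_state=setting.seed, n_jobs=1
    )


def _fit_per_bin(setting, X, y, bins, n_bins):
    """One regressor per occupied bin; empty bins simply stay uncovered."""
    per_bin = {}
    for b in range(n_bins):
        sel = bins == b
        if not sel.any():
            continue
        est = _make_regressor(setting)
        est.fit(X[sel], y[sel])
        per_bin[b] = est
    return per_bin

def _fit_numerical_group(setting, x, y, bins, n_bins):
    return {"kind": "numerical",
            "per_bin": _fit_per_bin(setting, x.reshape(-1, 1), y, bins, n_bins)}

def _fit_categorical_group(setting, cats, y, bins, n_bins):
    """Each category gets its own regression model: the configured regressor
    fit on a constant zero feature, so the prediction is its intercept."""
    per_cat = {}
    for cat in sorted(set(cats)):
        sel = np.asarray([c == cat for c in cats])
        zeros = np.zeros((int(sel.sum()), 1))
        per_cat[cat] = {
            "kind": "categorical_level",
            "per_bin": _fit_per_bin(setting, zeros, y[sel], bins[sel], n_bins),
        }
    return {"kind": "categorical", "per_cat": per_cat}


def _predict_group(group, cp_def, cp_value, bins, n_bins, uncovered_log=None):
    """Predicted bias (on the y scale) per pixel for one CP submodel group.

    ``cp_value`` is constant across a map's pixels, so each occupied bin
    needs a single regressor call. Unknown categories or unfitted bins
    contribute zero bias ("act like no bias")."""
    out = np.zeros(bins.shape, dtype=np.float64)
    if group is None:
        if uncovered_log is not None:
            uncovered_log.append((cp_def.name, "<all>"))
        return out
    if group["kind"] == "numerical":
        per_bin = group["per_bin"]
        row = np.asarray([[float(cp_value)]])
    else:
        level = group["per_cat"].get(str(cp_value))
        if level is None:
            if uncovered_log is not None:
                uncovered_log.append((cp_def.name, str(cp_value)))
            logger.info(
                "CP %r value %r not covered by training; skipped (no bias)",
                cp_def.name, cp_value,
            )
            return out
        per_bin = level["per_bin"]
        row = np.zeros((1, 1))
    for b in np.unique(bins):
        est = per_bin.get(int(b))
        if est is None:
            continue
        out[bins == b] = est.predict(row)[0]
    return out


# ---------------------------------------------------------------------------
# reference matching and targets
# ---------------------------------------------------------------------------

def matches_reference(record: T1MapRecord, cp: ConfounderDef) -> bool:
    value = record.cp_values.get(cp.name)
    if value is None:
        raise InputError(
            f"map {record.map_id!r} lacks CP {cp.name!r}"
        )
    if cp.representation == "numerical":
        return float(value) == float(cp.reference_value)
    return str(value) == str(cp.reference_value)


def compute_targets(train, cps, partition: BinPartition,
                    reference_selector=None) -> np.ndarray:
    """Per-bin target T1 values: pooled pixel means of training records whose
    selector CPs all equal their reference values.

    ``reference_selector`` lists CP names that must match (default: all).
    """
    by_name = {cp.name: cp for cp in cps}
    if reference_selector is None:
        reference_selector = [cp.name for cp in cps]
    selector = [by_name[name] for name in reference_selector]
    pooled = [
        rec.segmented_values()
        for rec in train
        if all(matches_reference(rec, cp) for cp in selector)
    ]
    names = ", ".join(cp.name for cp in selector)
    if not pooled:
        raise ConfigurationError(
            f"no training record matches the reference values of CP(s) {names}"
        )
    values = np.concatenate(pooled)
    bins = partition.assign(values)
    targets = np.empty(partition.n_bins, dtype=np.float64)
    for b in range(partition.n_bins):
        sel = bins == b
        if not sel.any():
            raise ConfigurationError(
                f"bin {b} contains no reference-matching pixels "
                f"(selector CPs: {names})"
            )
        targets[b] = values[sel].mean()
    if not np.all(np.isfinite(targets)) or not np.all(targets > 0):
        raise ConfigurationError(f"invalid per-bin targets {targets}")
    return targets


def _bias_y(values, targets, bins, y_type):
    """Dependent variable of the bias regression: apparent minus target, in
    ms (absolute) or as a fraction of the apparent value (relative)."""
    diff = values - targets[bins]
    if y_type == "absolute":
        return diff
    return diff / values


def _y_to_ms(pred, current, y_type):
    if y_type == "absolute":
        return pred
    return pred * current


# ---------------------------------------------------------------------------
# the model / results pair
# ---------------------------------------------------------------------------

class T1BiasModel:
    """Bias-estimation model specification bound to training data.

    Parameters
    ----------
    train : list of T1MapRecord
        Healthy training records with masks and complete CP vectors.
    setting : PipelineSetting
    cps : list of ConfounderDef
    """

    def __init__(self, train, setting: PipelineSetting, cps):
        if not train:
            raise InputError("training set is empty")
        names = [cp.name for cp in cps]
        if len(set(names)) != len(names):
            raise ConfigurationError(f"duplicate CP names: {names}")
        order = setting.cp_order or tuple(names)
        if sorted(order) != sorted(names):
            raise ConfigurationError(
                f"cp_order {order} is not a permutation of the CP set {names}"
            )
        for rec in train:
            rec.validate()
            missing = [n for n in names if n not in rec.cp_values]
            if missing:
                raise InputError(
                    f"map {rec.map_id!r} lacks CP value(s) {missing}"
                )
        self.train = list(train)
        self.setting = PipelineSetting(**{**setting.to_dict(),
                                          "cp_order": order})
        self.cps = list(cps)

    # -- helpers -----------------------------------------------------------
    def _cp(self, name) -> ConfounderDef:
        return next(cp for cp in self.cps if cp.name == name)

    def _pooled(self, records):
        """(values, record index, cp value broadcaster) over pooled pixels."""
        chunks = [rec.segmented_values() for rec in records]
        values = np.concatenate(chunks)
        owner = np.repeat(np.arange(len(records)), [len(c) for c in chunks])
        return values, owner

    def _fingerprint(self) -> dict:
        h = hashlib.sha256()
        n_pixels = 0
        for rec in sorted(self.train, key=lambda r: r.map_id):
            seg = rec.segmented_values()
            n_pixels += seg.size
            h.update(rec.map_id.encode())
            h.update(seg.tobytes())
            h.update(repr(sorted(rec.cp_values.items())).encode())
        return {
            "n_maps": len(self.train),
            "n_subjects": len({r.subject_id for r in self.train}),
            "n_pixels": int(n_pixels),
            "sha256": h.hexdigest(),
        }

    # -- fitting -----------------------------------------------------------
    def fit(self) -> "FittedPipeline":
        setting = self.setting
        pooled, _ = self._pooled(self.train)
        partition = fit_partition(pooled, setting.n_bins, setting.cluster_type,
                                  setting.seed)
        targets = compute_targets(self.train, self.cps, partition)
        uncovered: list[tuple[str, str]] = []
        codebooks: dict[str, dict[str, int]] = {}

        if setting.mode == "ensemble":
            submodels = self._fit_ensemble(partition, targets, codebooks)
        elif setting.mode == "individual":
            submodels = self._fit_individual(partition, targets, uncovered)
        else:
            submodels = self._fit_cascaded(partition, targets, uncovered)

        return FittedPipeline(
            setting=setting,
            cps=list(self.cps),
            partition=partition,
            per_bin_targets=targets,
            submodels=submodels,
            category_codebooks=codebooks,
            training_fingerprint=self._fingerprint(),
            uncovered=uncovered,
        )

    def _fit_one_cp(self, cp, records, current_values, owner, partition,
                    targets, uncovered):
        """Fit one CP's submodel group on the given (possibly partially
        standardised) pixel values."""
        setting = self.setting
        if len(records) == 0:
            uncovered.append((cp.name, "<all>"))
            logger.warning(
                "CP %r has no usable training subset in %s mode; it will "
                "act like no bias", cp.name, setting.mode,
            )
            return None
        bins = partition.assign(current_values)
        y = _bias_y(current_values, targets, bins, setting.y_type)
        if cp.representation == "numerical":
            x = np.asarray(
                [float(records[i].cp_values[cp.name]) for i in owner]
            )
            return _fit_numerical_group(setting, x, y, bins, partition.n_bins)
        cats = [str(records[i].cp_values[cp.name]) for i in owner]
        return _fit_categorical_group(setting, cats, y, bins, partition.n_bins)

    def _fit_individual(self, partition, targets, uncovered):
        submodels = {}
        for name in self.setting.cp_order:
            cp = self._cp(name)
            others = [c for c in self.cps if c.name != name]
            subset = [
                rec for rec in self.train
                if all(matches_reference(rec, o) for o in others)
            ]
            if subset:
                values, owner = self._pooled(subset)
            else:
                values, owner = np.empty(0), np.empty(0, dtype=int)
            submodels[name] = self._fit_one_cp(
                cp, subset, values, owner, partition, targets, uncovered
            )
        return submodels

    def _fit_cascaded(self, partition, targets, uncovered):
        setting = self.setting
        submodels = {}
        current = [rec.segmented_values() for rec in self.train]
        order = list(setting.cp_order)
        for k, name in enumerate(order):
            cp = self._cp(name)
            later = [self._cp(n) for n in order[k + 1:]]
            idx = [
                i for i, rec in enumerate(self.train)
                if all(matches_reference(rec, c) for c in later)
            ]
            subset = [self.train[i] for i in idx]
            if subset:
                chunks = [current[i] for i in idx]
                values = np.concatenate(chunks)
                owner = np.repeat(np.arange(len(subset)),
                                  [len(c) for c in chunks])
            else:
                values, owner = np.empty(0), np.empty(0, dtype=int)
            group = self._fit_one_cp(
                cp, subset, values, owner, partition, targets, uncovered
            )
            submodels[name] = group
            # standardise every training map for this CP before the next fit
            for i, rec in enumerate(self.train):
                bins = partition.assign(current[i])
                pred = _predict_group(group, cp, rec.cp_values[name], bins,
                                      partition.n_bins)
                current[i] = current[i] - _y_to_ms(pred, current[i],
                                                   setting.y_type)
        return submodels

    def _fit_ensemble(self, partition, targets, codebooks):
        setting = self.setting
        for cp in self.cps:
            if cp.representation == "categorical":
                labels = sorted(
                    {str(rec.cp_values[cp.name]) for rec in self.train}
                )
                codebooks[cp.name] = {lab: i for i, lab in enumerate(labels)}
        values, owner = self._pooled(self.train)
        bins = partition.assign(values)
        y = _bias_y(values, targets, bins, setting.y_type)
        X = np.empty((values.size, len(setting.cp_order)))
        for j, name in enumerate(setting.cp_order):
            cp = self._cp(name)
            if cp.representation == "numerical":
                col = [float(self.train[i].cp_values[name]) for i in owner]
            else:
                book = codebooks[name]
                col = [book[str(self.train[i].cp_values[name])] for i in owner]
            X[:, j] = col
        return {"per_bin": _fit_per_bin(setting, X, y, bins, partition.n_bins)}


class FittedPipeline:
    """Results object of :meth:`T1BiasModel.fit`.

    Carries the fitted bias estimators, the bin partition, per-bin target
    values, category codebooks (ensemble mode), coverage notes and a
    training fingerprint; exposes :meth:`estimate_bias`,
    :meth:`standardise_map`, :meth:`summary`, and persistence via
    :meth:`save` / :meth:`load`.
    """

    def __init__(self, setting, cps, partition, per_bin_targets, submodels,
                 category_codebooks, training_fingerprint, uncovered):
        self.setting = setting
        self.cps = cps
        self.partition = partition
        self.per_bin_targets = np.asarray(per_bin_targets, dtype=np.float64)
        self.submodels = submodels
        self.category_codebooks = category_codebooks
        self.training_fingerprint = training_fingerprint
        self.uncovered = list(uncovered)

    def _cp(self, name) -> ConfounderDef:
        return next(cp for cp in self.cps if cp.name == name)

    # -- application -------------------------------------------------------
    def estimate_bias(self, values, cp_values) -> list[tuple[str, np.ndarray]]:
        """Per-pixel bias components in ms for one map's segmented values.

        Individual/cascaded modes return one component per CP in
        ``cp_order`` (unknown categorical values contribute zero bias);
        ensemble mode returns a single combined component and raises
        :class:`ApplicationError` for categories absent from the codebook.
        """
        setting = self.setting
        values = np.asarray(values, dtype=np.float64)
        missing = [n for n in setting.cp_order if n not in cp_values]
        if missing:
            raise InputError(f"cp_values lacks {missing}")

        if setting.mode == "ensemble":
            bins = self.partition.assign(values)
            row = np.empty((1, len(setting.cp_order)))
            for j, name in enumerate(setting.cp_order):
                cp = self._cp(name)
                if cp.representation == "numerical":
                    row[0, j] = float(cp_values[name])
                else:
                    book = self.category_codebooks.get(name, {})
                    label = str(cp_values[name])
                    if label not in book:
                        raise ApplicationError(
                            f"ensemble mode cannot standardise unseen "
                            f"category {label!r} of CP {name!r}"
                        )
                    row[0, j] = book[label]
            pred = np.zeros_like(values)
            for b in np.unique(bins):
                est = self.submodels["per_bin"].get(int(b))
                if est is not None:
                    pred[bins == b] = est.predict(row)[0]
            return [(_ENSEMBLE_COMPONENT, _y_to_ms(pred, values,
                                                   setting.y_type))]

        components = []
        if setting.mode == "individual":
            bins = self.partition.assign(values)
            for name in setting.cp_order:
                cp = self._cp(name)
                pred = _predict_group(self.submodels[name], cp,
                                      cp_values[name], bins,
                                      self.partition.n_bins)
                components.append((name, _y_to_ms(pred, values,
                                                  setting.y_type)))
        else:  # cascaded: component k uses the value corrected by 1..k-1
            current = values.copy()
            for name in setting.cp_order:
                cp = self._cp(name)
                bins = self.partition.assign(current)
                pred = _predict_group(self.submodels[name], cp,
                                      cp_values[name], bins,
                                      self.partition.n_bins)
                comp = _y_to_ms(pred, current, setting.y_type)
                components.append((name, comp))
                current = current - comp
        return components

    def standardise_map(self, record: T1MapRecord) -> StandardisationResult:
        """Standardise one map: estimate the CP-induced bias of its
        segmented pixels and subtract it."""
        record.validate()
        values = record.segmented_values()
        components = self.estimate_bias(values, record.cp_values)
        total = np.sum([comp for _, comp in components], axis=0)
        standardised = values - total
        return StandardisationResult(
            map_id=record.map_id,
            subject_id=record.subject_id,
            cohort=record.cohort,
            cp_values=dict(record.cp_values),
            values_original=values,
            bias_components=components,
            values_standardised=standardised,
            mean_before=float(values.mean()),
            mean_after=float(standardised.mean()),
        )

    def standardise(self, records) -> list[StandardisationResult]:
        return [self.standardise_map(rec) for rec in records]

    # -- persistence (implemented in t1std.persistence) ---------------------
    def save(self, path, include_fingerprint: bool = True):
        from .persistence import save_pipeline
        return save_pipeline(self, path, include_fingerprint)

    @classmethod
    def load(cls, path) -> "FittedPipeline":
        from .persistence import load_pipeline
        return load_pipeline(path)

    # -- reporting ----------------------------------------------------------
    def summary(self) -> str:
        s = self.setting
        lines = [
            "Standardisation pipeline (fitted)",
            "=" * 46,
            f"regression type : {s.regression_type}",
            f"y type          : {s.y_type}",
            f"mode            : {s.mode}",
            f"bins            : {s.n_bins} ({s.cluster_type})"
            if s.n_bins > 1 else "bins            : 1",
            f"CP order        : {', '.join(s.cp_order)}",
            f"seed            : {s.seed}",
            "-" * 46,
            "per-bin targets (ms): "
            + ", ".join(f"{t:.2f}" for t in self.per_bin_targets),
            f"training maps   : {self.training_fingerprint['n_maps']} "
            f"({self.training_fingerprint['n_pixels']} pixels, "
            f"{self.training_fingerprint['n_subjects']} subjects)",
        ]
        for cp in self.cps:
            ref = cp.reference_value
            lines.append(f"CP {cp.name:<12} [{cp.representation}] "
                         f"reference = {ref}")
        if self.uncovered:
            notes = ", ".join(f"{c}={v}" for c, v in self.uncovered)
            lines.append(f"uncovered (act like no bias): {notes}")
        return "\n".join(lines)

    def __repr__(self) -> str:
        return f"<FittedPipeline {self.setting.label()}>"


def fit_pipeline(train, setting: PipelineSetting, cps) -> FittedPipeline:
    """Convenience wrapper: build a :class:`T1BiasModel` and fit it."""
    return T1BiasModel(train, setting, cps).fit()
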