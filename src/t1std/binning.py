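"""One-dimensional binning of pooled T1 values.

Bins let the bias regression depend on the T1 value itself (high values may
be confounded differently from low ones). Eight clustering algorithms are
supported; every fitted partition is reduced to ordered half-open intervals
``[lo, hi)`` covering the whole real line, so application-time assignment is
deterministic, exhaustive and monotone.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError

CLUSTER_TYPES = (
    "agglomerative_average",
    "agglomerative_complete",
    "agglomerative_single",
    "agglomerative_ward",
    "equal_distant",
    "equal_size",
    "gaussian_mixture",
    "k_means",
)

#: sklearn agglomerative clustering is O(n^2); larger pools are subsampled
#: deterministically before fitting the clustering-based partitions.
MAX_CLUSTER_FIT_SAMPLES = 5000


@dataclass(frozen=True)
class BinPartition:
    """Ordered exhaustive partition of the reals into ``n_bins`` intervals.

    ``boundaries`` holds the ``n_bins - 1`` inner cut points; interval k is
    ``[boundaries[k-1], boundaries[k])`` with the first/last interval
    extended to -inf/+inf. A value equal to a boundary belongs to the upper
    bin (half-open convention).
    """

    n_bins: int
    cluster_type: str
    boundaries: tuple[float, ...]
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.boundaries) != self.n_bins - 1:
            raise ConfigurationError(
                f"{self.n_bins} bins need {self.n_bins - 1} boundaries, "
                f"got {len(self.boundaries)}"
            )
        b = np.asarray(self.boundaries, dtype=float)
        if b.size and (not np.all(np.isfinite(b)) or np.any(np.diff(b) <= 0)):
            raise ConfigurationError(
                f"bin boundaries must be finite and strictly increasing: {b}"
            )

    @property
    def intervals(self) -> list[tuple[float, float]]:
        edges = [-np.inf, *self.boundaries, np.inf]
        return [(edges[i], edges[i + 1]) for i in range(self.n_bins)]

    def assign(self, values) -> np.ndarray:
        """Bin index for each value; exhaustive, so this never fails."""
        v = np.asarray(values, dtype=float)
        return np.searchsorted(np.asarray(self.boundaries), v, side="right")

    def to_dict(self) -> dict:
        return {
            "n_bins": self.n_bins,
            "cluster_type": self.cluster_type,
            "boundaries": list(self.boundaries),
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BinPartition":
        return cls(
            n_bins=int(d["n_bins"]),
            cluster_type=d["cluster_type"],
            boundaries=tuple(float(x) for x in d["boundaries"]),
            seed=int(d["seed"]),
        )


def assign_bin(partition: BinPartition, values) -> np.ndarray:
    return partition.assign(values)


def _cluster_labels(values: np.ndarray, n_bins: int, cluster_type: str,
                    seed: int) -> np.ndarray:
    from sklearn.cluster import AgglomerativeClustering, KMeans
    from sklearn.mixture import GaussianMixture

    X = values.reshape(-1, 1)
    if cluster_type.startswith("agglomerative_"):
        linkage = cluster_type.split("_", 1)[1]
        model = AgglomerativeClustering(n_clusters=n_bins, linkage=linkage)
        return model.fit_predict(X)
    if cluster_type == "k_means":
        model = KMeans(n_clusters=n_bins, random_state=seed, n_init=10)
        return model.fit_predict(X)
    if cluster_type == "gaussian_mixture":
        model = GaussianMixture(n_components=n_bins, random_state=seed)
        return model.fit(X).predict(X)
    raise ConfigurationError(f"unknown cluster_type {cluster_type!r}")


def _boundaries_from_labels(values: np.ndarray, labels: np.ndarray,
                            n_bins: int) -> np.ndarray:
    """Midpoints between adjacent clusters' extreme members, clusters ordered
    by ascending mean. Ties at a boundary go to the upper bin (half-open)."""
    groups = []
    for lab in np.unique(labels):
        members = values[labels == lab]
        groups.append((members.mean(), members.min(), members.max()))
    if len(groups) < n_bins:
        raise ConfigurationError(
            f"clustering produced only {len(groups)} non-empty clusters "
            f"for {n_bins} bins"
        )
    groups.sort(key=lambda g: g[0])
    bounds = np.array(
        [(groups[k][2] + groups[k + 1][1]) / 2.0 for k in range(n_bins - 1)]
    )
    if np.any(np.diff(bounds) <= 0):
        raise ConfigurationError(
            f"clusters are not separable into ordered intervals "
            f"(boundaries {bounds})"
        )
    return bounds


def fit_partition(values, n_bins: int, cluster_type: str = "equal_distant",
                  seed: int = 0) -> BinPartition:
    """Cluster pooled 1-D T1 values (ms) into ``n_bins`` ordered intervals.

    ``equal_distant`` slices [min, max] into bins of equal width;
    ``equal_size`` sorts the values and gives each bin the same count
    (occupancy differs by at most one); the remaining six algorithms come
    from scikit-learn and are reduced to intervals via midpoints between
    adjacent clusters' extreme members. More than ten bins is allowed but
    warned against — small bins are no longer representative.
    """
    v = np.asarray(values, dtype=float).ravel()
    if n_bins < 1:
        raise ConfigurationError(f"n_bins must be >= 1, got {n_bins}")
    if cluster_type not in CLUSTER_TYPES:
        raise ConfigurationError(f"unknown cluster_type {cluster_type!r}")
    if n_bins == 1:
        return BinPartition(1, cluster_type, (), seed)
    if v.size < n_bins:
        raise ConfigurationError(
            f"{n_bins} bins requested but only {v.size} values available"
        )
    if v.min() == v.max():
        raise ConfigurationError(
            "all values identical: a multi-bin partition is undefined"
        )
    if n_bins > 10:
        warnings.warn(
            f"{n_bins} bins requested; ten or fewer is recommended so each "
            f"bin stays representative",
            stacklevel=2,
        )

    if cluster_type == "equal_distant":
        lo, hi = v.min(), v.max()
        bounds = lo + (hi - lo) * np.arange(1, n_bins) / n_bins
    elif cluster_type == "equal_size":
        s = np.sort(v)
        chunks = np.array_split(s, n_bins)
        bounds = np.array(
            [(chunks[k][-1] + chunks[k + 1][0]) / 2.0 for k in range(n_bins - 1)]
        )
        if np.any(np.diff(bounds) <= 0) or np.any(bounds <= s[0]):
            raise ConfigurationError(
                "equal_size bins collapse on heavily tied values"
            )
    else:
        fit_v = v
        if v.size > MAX_CLUSTER_FIT_SAMPLES:
            rng = np.random.default_rng(seed)
            fit_v = rng.choice(v, size=MAX_CLUSTER_FIT_SAMPLES, replace=False)
        labels = _cluster_labels(fit_v, n_bins, cluster_type, seed)
        bounds = _boundaries_from_labels(fit_v, labels, n_bins)

    return BinPartition(n_bins, cluster_type, tuple(float(b) for b in bounds),
                        seed)
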