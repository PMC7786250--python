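"""Histogram-based imaging features of the voxel-wise NWU maps.

The per-voxel NWU values from the four 30x30 ratio maps are binned into an
N-grade discrete histogram (N = 8 by default) over [0, 1]:

    h(r_n) = Y_n,   n = 1 .. N

where r_n is the NWU grade (bin) and Y_n the number of voxels in it.  From
the count vector Y_1..Y_N five summary parameters are derived — population
standard deviation s, min-to-max slope, Shannon entropy H, skewness g and
excess kurtosis k — giving 13 imaging features (8 counts + 5 parameters).

The moment features are, deliberately, moments of the *grade-count vector*
(treating Y_1..Y_N as a univariate sample of length N), not of the raw map
values; ``on="values"`` computes the alternative reading.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping, Optional, Sequence

import numpy as np

from .patches import RatioMapSet

__all__ = [
    "NWUHistogram",
    "FeatureVector",
    "IMAGING_FEATURE_NAMES",
    "FEATURE_SETS",
    "build_histogram",
    "histogram_entropy",
    "vector_std",
    "vector_skewness",
    "vector_kurtosis",
    "histogram_slope",
    "assemble_features",
]

IMAGING_FEATURE_NAMES = (
    "y1", "y2", "y3", "y4", "y5", "y6", "y7", "y8",
    "std", "slope", "entropy", "skewness", "kurtosis",
)

FEATURE_SETS = ("nwu_clinical", "nwu_imaging", "nwu_clinical_imaging")
CLINICAL_NAMES = ("age", "gender", "nihss")


@dataclass(frozen=True)
class NWUHistogram:
    counts: np.ndarray          # Y_1..Y_N
    bin_edges: np.ndarray       # N + 1 boundaries over [0, 1]
    total: int

    @property
    def n_grades(self) -> int:
        return int(self.counts.size)

    @property
    def grades(self) -> np.ndarray:
        """Representative NWU value of each grade (bin midpoints)."""
        return (self.bin_edges[:-1] + self.bin_edges[1:]) / 2.0

    @property
    def proportions(self) -> np.ndarray:
        if self.total == 0:
            return np.zeros_like(self.counts, dtype=np.float64)
        return self.counts.astype(np.float64) / self.total


@dataclass(frozen=True)
class FeatureVector:
    """Ordered feature mapping for one subject.

    Ordering is fixed: NWU first, then the three clinical covariates when
    requested (age, gender, NIHSS), then the 13 imaging features
    (Y1..Y8, std, slope, entropy, skewness, kurtosis).
    """

    names: tuple[str, ...]
    values: np.ndarray
    feature_set: str
    degenerate: bool = False

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.names, self.values.tolist()))


def build_histogram(maps: RatioMapSet, n_grades: int = 8) -> NWUHistogram:
    """Equal-width N-grade histogram of the retained map voxels over [0, 1].

    Bins are half-open ``[e_i, e_{i+1})`` with the last bin closed at 1, so
    every retained voxel (all values lie in [0, 1] by construction) is
    counted exactly once.
    """
    if n_grades < 2:
        raise ValueError("n_grades must be >= 2")
    values = maps.values()
    if values.size == 0:
        raise ValueError("no retained voxels to histogram")
    edges = np.linspace(0.0, 1.0, n_grades + 1)
    counts, _ = np.histogram(values, bins=edges)  # numpy closes the last bin
    return NWUHistogram(counts=counts.astype(np.int64), bin_edges=edges,
                        total=int(values.size))


def histogram_entropy(
    p: Sequence[float] | np.ndarray, base: Literal["2", "e"] = "2"
) -> float:
    """Shannon entropy -sum p_n log p_n with 0 log 0 := 0 (base 2 default).

    For N = 8 grades the entropy lies in [0, 3] bits, maximal for the
    uniform histogram.
    """
    p = np.asarray(p, dtype=np.float64)
    if np.any(p < 0):
        raise ValueError("proportions must be non-negative")
    if p.sum() > 0 and not np.isclose(p.sum(), 1.0):
        raise ValueError("proportions must sum to 1")
    nz = p[p > 0]
    log = np.log2 if base == "2" else np.log
    return float(-(nz * log(nz)).sum())


def vector_std(y: Sequence[float] | np.ndarray) -> float:
    """Population (1/N) standard deviation of a univariate vector."""
    y = np.asarray(y, dtype=np.float64)
    return float(y.std(ddof=0))


def vector_skewness(y: Sequence[float] | np.ndarray) -> float:
    """Population skewness g = sum (Y_i - mean)^3 / (N s^3).

    Zero for any vector symmetric about its mean; a zero-variance vector is
    degenerate and reported as 0.
    """
    y = np.asarray(y, dtype=np.float64)
    if y.size < 2:
        raise ValueError("need at least two values")
    s = y.std(ddof=0)
    if s == 0:
        return 0.0
    d = y - y.mean()
    return float((d**3).sum() / (y.size * s**3))


def vector_kurtosis(y: Sequence[float] | np.ndarray) -> float:
    """Population excess kurtosis k = sum (Y_i - mean)^4 / (N s^4) - 3.

    Zero for the standard normal, positive for heavy tails; the minimum,
    attained by a symmetric two-point vector, is -2.
    """
    y = np.asarray(y, dtype=np.float64)
    if y.size < 2:
        raise ValueError("need at least two values")
    s = y.std(ddof=0)
    if s == 0:
        return 0.0
    d = y - y.mean()
    return float((d**4).sum() / (y.size * s**4) - 3.0)


def histogram_slope(y: Sequence[float] | np.ndarray) -> float:
    """Gradient between the minimum and maximum points of the count vector.

    slope = (Y_max - Y_min) / (index_max - index_min) with 1-based grade
    indices, first occurrence on ties; a constant vector has slope 0.
    """
    y = np.asarray(y, dtype=np.float64)
    if y.size < 2:
        raise ValueError("need at least two values")
    i_min = int(np.argmin(y))
    i_max = int(np.argmax(y))
    if i_min == i_max:  # constant vector
        return 0.0
    return float((y[i_max] - y[i_min]) / (i_max - i_min))


def _encode_gender(gender) -> float:
    if isinstance(gender, str):
        g = gender.strip().upper()
        if g in ("F", "FEMALE", "1"):
            return 1.0
        if g in ("M", "MALE", "0"):
            return 0.0
        raise ValueError(f"unrecognised gender {gender!r}")
    return float(gender)


def assemble_features(
    hist: NWUHistogram,
    ip_nwu: float,
    clinical: Optional[Mapping[str, object]] = None,
    feature_set: str = "nwu_clinical_imaging",
    moments_on: Literal["counts", "values"] = "counts",
    raw_values: Optional[np.ndarray] = None,
) -> FeatureVector:
    """Assemble the requested feature set for one subject.

    ``nwu_clinical`` -> (NWU, age, gender, NIHSS);
    ``nwu_imaging`` -> NWU plus the 13 imaging features;
    ``nwu_clinical_imaging`` -> all 17.  Gender is encoded F=1 / M=0.
    """
    if feature_set not in FEATURE_SETS:
        raise ValueError(f"unknown feature set {feature_set!r}")
    names: list[str] = ["nwu"]
    values: list[float] = [float(ip_nwu)]

    if feature_set in ("nwu_clinical", "nwu_clinical_imaging"):
        if clinical is None:
            raise ValueError(f"feature set {feature_set!r} requires clinical covariates")
        missing = [k for k in CLINICAL_NAMES if k not in clinical]
        if missing:
            raise ValueError(f"missing clinical covariates: {missing}")
        names += list(CLINICAL_NAMES)
        values += [
            float(clinical["age"]),  # type: ignore[arg-type]
            _encode_gender(clinical["gender"]),
            float(clinical["nihss"]),  # type: ignore[arg-type]
        ]

    degenerate = False
    if feature_set in ("nwu_imaging", "nwu_clinical_imaging"):
        y = hist.counts.astype(np.float64)
        if moments_on == "values":
            if raw_values is None:
                raise ValueError("moments_on='values' requires raw_values")
            moment_sample = np.asarray(raw_values, dtype=np.float64)
        else:
            moment_sample = y
        s = vector_std(moment_sample)
        degenerate = s == 0
        names += list(IMAGING_FEATURE_NAMES)
        values += [
            *y.tolist(),
            vector_std(y),
            histogram_slope(y),
            histogram_entropy(hist.proportions),
            vector_skewness(moment_sample),
            vector_kurtosis(moment_sample),
        ]
    return FeatureVector(
        names=tuple(names),
        values=np.asarray(values, dtype=np.float64),
        feature_set=feature_set,
        degenerate=degenerate,
    )
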