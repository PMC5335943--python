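"""Feature extraction: Hjorth slope descriptors, filtered-signal vectors,
and mutual-information feature ranking.

Three feature families feed the emotion classifiers:

``filtered``
    The broadband-filtered samples of all 14 channels concatenated
    channel-major; a full default epoch gives 14 x 192 = 2688 values.
``hjorth14``
    Hjorth parameters (activity, mobility, complexity) of every channel in
    every clinical band: 14 x 4 x 3 = 168 values.
``hjorth6``
    The same descriptors restricted to six frontal/central electrodes:
    6 x 4 x 3 = 72 values.

Hjorth's normalised slope descriptors are time-domain spectral summaries:
activity is the signal's population variance, mobility the square root of
the variance ratio of the first difference to the signal (an rms angular
frequency, in radians per sample since differences are not scaled by the
sampling interval), and complexity the mobility of the first difference
divided by the mobility of the signal (1 for a pure sinusoid, larger for
broader spectra).
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from ._errors import DegenerateSignalError, InvalidArgumentError
from .preprocessing import DEFAULT_BANDS, Band, BandFilteredEpoch, Epoch
from .synth import DEFAULT_MONTAGE, EmotionLabel, Montage

__all__ = [
    "HjorthTriple",
    "hjorth",
    "FeatureVector",
    "ChannelSubset",
    "FRONTAL_CENTRAL_6",
    "filtered_feature",
    "hjorth_feature",
    "extract_features",
    "mi_rank",
    "mutual_information",
    "write_feature_csv",
    "read_feature_csv",
]

_PARAM_NAMES = ("activity", "mobility", "complexity")


@dataclass(frozen=True)
class HjorthTriple:
    activity: float
    mobility: float
    complexity: float

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.activity, self.mobility, self.complexity)


def hjorth(signal: np.ndarray) -> HjorthTriple:
    """Compute the three Hjorth descriptors of a single-channel signal.

    Uses population variances and unscaled first differences.  A constant
    signal has zero variance, which leaves mobility and complexity
    undefined: that raises :class:`DegenerateSignalError` here (batch
    callers map it to a sentinel instead, see :func:`hjorth_feature`).
    A perfectly linear signal (constant first difference) gets mobility 0
    and, by convention, complexity 0.
    """
    y = np.asarray(signal, dtype=float).ravel()
    if y.size < 3:
        raise InvalidArgumentError(f"need at least 3 samples, got {y.size}")
    var_y = float(np.var(y))
    if var_y == 0.0:
        raise DegenerateSignalError("constant signal: Hjorth mobility undefined")
    d1 = np.diff(y)
    var_d1 = float(np.var(d1))
    mobility = np.sqrt(var_d1 / var_y)
    if var_d1 == 0.0:
        return HjorthTriple(var_y, 0.0, 0.0)
    d2 = np.diff(d1)
    mobility_d1 = np.sqrt(float(np.var(d2)) / var_d1)
    return HjorthTriple(var_y, float(mobility), float(mobility_d1 / mobility))


_SENTINEL = HjorthTriple(0.0, 0.0, 0.0)


def _hjorth_or_sentinel(y: np.ndarray, context: str) -> HjorthTriple:
    try:
        return hjorth(y)
    except DegenerateSignalError:
        warnings.warn(
            f"degenerate (constant) signal in {context}; using sentinel (0, 0, 0)",
            RuntimeWarning,
            stacklevel=3,
        )
        return _SENTINEL


@dataclass
class FeatureVector:
    """One extracted feature vector with provenance."""

    family: str  # filtered | hjorth14 | hjorth6
    values: np.ndarray
    layout: str
    label: EmotionLabel | None = None
    feature_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()

    def __len__(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class ChannelSubset:
    name: str
    channels: tuple[str, ...]

    def validate_against(self, montage: Montage) -> None:
        missing = [c for c in self.channels if c not in montage.channel_names]
        if missing:
            raise InvalidArgumentError(
                f"subset {self.name!r} channels {missing} absent from montage"
            )


#: Default six-electrode frontal/central subset (the montage has no pure
#: central electrodes, so the six most frontal-central labels are used).
FRONTAL_CENTRAL_6 = ChannelSubset(
    "frontal_central_6", ("AF3", "F3", "FC5", "FC6", "F4", "AF4")
)

FULL_14 = ChannelSubset("all_14", DEFAULT_MONTAGE.channel_names)


def filtered_feature(epoch: Epoch, montage: Montage = DEFAULT_MONTAGE) -> FeatureVector:
    """Flatten a broadband-filtered epoch channel-major into one vector.

    Callers are expected to band-limit the epoch to 0.5-30 Hz first (see
    :func:`emorec.preprocessing.broadband`).  A full default epoch yields
    exactly 2688 values.
    """
    if epoch.montage.channel_names != montage.channel_names:
        raise InvalidArgumentError(
            f"epoch montage {epoch.montage.channel_names} does not match "
            f"expected montage {montage.channel_names}"
        )
    return FeatureVector(
        family="filtered",
        values=epoch.data.reshape(-1),
        layout="channel-major: all samples of channel 0, then channel 1, ...",
        label=epoch.label,
    )


def hjorth_feature(
    decomposition: dict[str, BandFilteredEpoch],
    subset: ChannelSubset | None = None,
    bands: tuple[Band, ...] = DEFAULT_BANDS,
) -> FeatureVector:
    """Hjorth descriptors for each (channel, band) pair, flattened.

    Ordering is channel-major, then band (delta..beta), then
    (activity, mobility, complexity); lengths are 168 for the full montage
    and 72 for the six-channel subset.  Degenerate channels are mapped to
    the (0, 0, 0) sentinel with a warning so one flat electrode cannot
    abort a session.
    """
    missing = [b.name for b in bands if b.name not in decomposition]
    if missing:
        raise InvalidArgumentError(f"decomposition is missing bands {missing}")
    any_band = decomposition[bands[0].name]
    epoch = any_band.parent
    subset = subset or ChannelSubset("all_14", epoch.montage.channel_names)
    subset.validate_against(epoch.montage)

    values: list[float] = []
    names: list[str] = []
    for channel in subset.channels:
        ci = epoch.montage.index(channel)
        for band in bands:
            triple = _hjorth_or_sentinel(
                decomposition[band.name].data[ci], f"channel {channel}, band {band.name}"
            )
            values.extend(triple.as_tuple())
            names.extend(f"{channel}_{band.name}_{p}" for p in _PARAM_NAMES)
    family = "hjorth6" if len(subset.channels) == 6 else "hjorth14"
    return FeatureVector(
        family=family,
        values=np.asarray(values),
        layout="channel-major, then band (delta,theta,alpha,beta), "
        "then (activity, mobility, complexity)",
        label=epoch.label,
        feature_names=tuple(names),
    )


def extract_features(
    epochs: list[Epoch],
    family: str = "hjorth14",
    subset: ChannelSubset = FRONTAL_CENTRAL_6,
    bands: tuple[Band, ...] = DEFAULT_BANDS,
) -> tuple[np.ndarray, list[EmotionLabel | None], tuple[str, ...] | None]:
    """Vectorise a list of epochs into an ``n_epochs x n_features`` matrix."""
    from .preprocessing import broadband, decompose

    rows, labels, names = [], [], None
    for epoch in epochs:
        if family == "filtered":
            fv = filtered_feature(broadband(epoch), montage=epoch.montage)
        elif family == "hjorth14":
            fv = hjorth_feature(decompose(epoch, bands), subset=None, bands=bands)
        elif family == "hjorth6":
            fv = hjorth_feature(decompose(epoch, bands), subset=subset, bands=bands)
        else:
            raise InvalidArgumentError(
                f"unknown feature family {family!r}; "
                "expected filtered, hjorth14 or hjorth6"
            )
        rows.append(fv.values)
        labels.append(fv.label)
        names = fv.feature_names
    return np.asarray(rows), labels, names


# ---------------------------------------------------------------------------
# Mutual-information ranking


def _equal_frequency_bins(column: np.ndarray, n_bins: int) -> np.ndarray:
    """Discretise a feature column into at most ``n_bins`` quantile bins."""
    qs = np.quantile(column, np.arange(1, n_bins) / n_bins)
    edges = np.unique(qs)
    return np.searchsorted(edges, column, side="right")


def mutual_information(column: np.ndarray, labels: np.ndarray, n_bins: int = 8) -> float:
    """Plug-in mutual information (nats) between a binned feature and labels.

    The feature is discretised into equal-frequency bins; no bias
    correction is applied — adequate for ranking, not for unbiased
    estimation.  A constant feature has a single bin and MI exactly 0.
    """
    binned = _equal_frequency_bins(np.asarray(column, dtype=float), n_bins)
    b_vals, b_idx = np.unique(binned, return_inverse=True)
    l_vals, l_idx = np.unique(labels, return_inverse=True)
    counts = np.zeros((b_vals.size, l_vals.size))
    np.add.at(counts, (b_idx, l_idx), 1.0)
    p = counts / counts.sum()
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = p * np.log(p / (px * py))
    return float(np.nansum(terms))


def mi_rank(
    feature_matrix: np.ndarray, labels: list | np.ndarray, n_bins: int = 8
) -> np.ndarray:
    """Rank feature indices by decreasing mutual information with the label.

    Ties are broken by ascending feature index, so the ranking is
    deterministic and permutation-equivariant in the sample order.
    """
    X = np.asarray(feature_matrix, dtype=float)
    y = np.asarray([getattr(l, "value", l) for l in labels])
    if X.ndim != 2:
        raise InvalidArgumentError("feature matrix must be 2-D")
    if y.shape[0] != X.shape[0]:
        raise InvalidArgumentError(
            f"{X.shape[0]} samples but {y.shape[0]} labels"
        )
    if np.unique(y).size < 2:
        raise InvalidArgumentError("need at least 2 classes to rank features")
    if X.shape[0] < 10:
        raise InvalidArgumentError(f"need at least 10 samples, got {X.shape[0]}")
    mi = np.array([mutual_information(X[:, j], y, n_bins) for j in range(X.shape[1])])
    return np.argsort(-mi, kind="stable")


# ---------------------------------------------------------------------------
# Feature CSV interchange (header names each feature "<channel>_<band>_<param>")


def write_feature_csv(
    path: str | Path,
    matrix: np.ndarray,
    labels: list[EmotionLabel | None],
    feature_names: tuple[str, ...] | None = None,
) -> None:
    matrix = np.asarray(matrix, dtype=float)
    if feature_names is None:
        feature_names = tuple(f"f{j}" for j in range(matrix.shape[1]))
    with Path(path).open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow([*feature_names, "label"])
        for row, label in zip(matrix, labels):
            writer.writerow([*(f"{v:.10g}" for v in row), getattr(label, "value", label) or ""])


def read_feature_csv(path: str | Path) -> tuple[np.ndarray, list[EmotionLabel | None], tuple[str, ...]]:
    with Path(path).open("r", encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if not header or header[-1] != "label":
            raise InvalidArgumentError("feature CSV must end with a 'label' column")
        names = tuple(header[:-1])
        rows, labels = [], []
        for rec in reader:
            rows.append([float(v) for v in rec[:-1]])
            labels.append(EmotionLabel(rec[-1]) if rec[-1] else None)
    return np.asarray(rows), labels, names
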