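"""Fixed-length feature vectors from kinematic channel sets.

Two interchangeable feature families:

* a deterministic per-channel **statistical catalogue** (moments, peaks,
  autocorrelation, trend, entropy, ... — 21 named descriptors), applied to
  each channel independently and concatenated, giving ``n_channels x 21``
  features named ``<channel>__<descriptor>``;
* a **random convolutional kernel transform**: ``n_kernels`` kernels with
  length drawn from {7, 9, 11}, standard-normal mean-centred weights, bias
  uniform on [-1, 1], dyadic dilation and optional zero padding, each
  emitting two features per channel — the maximum of the activation map and
  the proportion of positive values (PPV).  Kernel input is cropped (or
  last-value padded) to a fixed length, 400 frames by default.

Both are exposed functionally and as sklearn-style transformers
(:class:`CatalogueFeaturizer`, :class:`RocketFeaturizer`).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import EmptyInputError, InvalidArgumentError, SchemaError
from .kinematics import ChannelSet

logger = logging.getLogger(__name__)


@dataclass
class FeatureVector:
    """Named feature values with channel-of-origin provenance."""

    values: pd.Series
    provenance: pd.DataFrame  # index: feature name; columns: channel, category, descriptor

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise SchemaError("duplicate feature names")
        if not self.values.index.equals(self.provenance.index):
            raise SchemaError("provenance index does not match feature names")

    def __len__(self) -> int:
        return len(self.values)


# ---------------------------------------------------------------------------
# Statistical catalogue
# ---------------------------------------------------------------------------


def _longest_run(mask: np.ndarray) -> int:
    best = run = 0
    for m in mask:
        run = run + 1 if m else 0
        best = max(best, run)
    return best


def _autocorr(x: np.ndarray, lag: int) -> float:
    if len(x) <= lag or np.var(x) == 0:
        return 0.0
    a, b = x[:-lag], x[lag:]
    if np.std(a) == 0 or np.std(b) == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def _linear_fit(x: np.ndarray) -> tuple[float, float]:
    t = np.arange(len(x), dtype=float)
    slope, intercept = np.polyfit(t, x, 1)
    fitted = slope * t + intercept
    ss_tot = float(np.sum((x - x.mean()) ** 2))
    if ss_tot == 0:
        return float(slope), 0.0
    r2 = 1.0 - float(np.sum((x - fitted) ** 2)) / ss_tot
    return float(slope), r2


def _sample_entropy(x: np.ndarray, m: int = 2, r_frac: float = 0.2) -> float:
    """Sample entropy with embedding dimension m and tolerance 0.2·SD."""
    n = len(x)
    sd = np.std(x)
    if sd == 0 or n <= m + 1:
        return 0.0
    r = r_frac * sd

    def _count(mm: int) -> int:
        emb = np.lib.stride_tricks.sliding_window_view(x, mm)
        d = np.max(np.abs(emb[:, None, :] - emb[None, :, :]), axis=2)
        return int((d[np.triu_indices(len(emb), k=1)] <= r).sum())

    b = _count(m)
    a = _count(m + 1)
    if a == 0 or b == 0:
        return 0.0
    return float(-math.log(a / b))


def _n_peaks(x: np.ndarray) -> float:
    if len(x) < 3:
        return 0.0
    mid = x[1:-1]
    return float(np.sum((mid > x[:-2]) & (mid > x[2:])))


def _mean_crossings(x: np.ndarray) -> float:
    s = np.sign(x - x.mean())
    s = s[s != 0]
    return float(np.sum(s[1:] != s[:-1])) if len(s) > 1 else 0.0


def _skewness(x: np.ndarray) -> float:
    sd = x.std()
    return float(np.mean(((x - x.mean()) / sd) ** 3)) if sd > 0 else 0.0


def _kurtosis(x: np.ndarray) -> float:
    sd = x.std()
    return float(np.mean(((x - x.mean()) / sd) ** 4) - 3.0) if sd > 0 else 0.0


#: descriptor name -> callable; the catalogue is pinned so that feature
#: dimensions and names are stable across library versions.
CATALOGUE: dict[str, callable] = {
    "mean": lambda x: float(np.mean(x)),
    "variance": lambda x: float(np.var(x)),
    "std": lambda x: float(np.std(x)),
    "min": lambda x: float(np.min(x)),
    "max": lambda x: float(np.max(x)),
    "median": lambda x: float(np.median(x)),
    "iqr": lambda x: float(np.percentile(x, 75) - np.percentile(x, 25)),
    "skewness": _skewness,
    "kurtosis": _kurtosis,
    "n_peaks": _n_peaks,
    "n_mean_crossings": _mean_crossings,
    "abs_energy": lambda x: float(np.sum(x * x)),
    "mean_abs_change": lambda x: float(np.mean(np.abs(np.diff(x)))),
    "autocorr_lag_1": lambda x: _autocorr(x, 1),
    "autocorr_lag_5": lambda x: _autocorr(x, 5),
    "autocorr_lag_10": lambda x: _autocorr(x, 10),
    "linear_slope": lambda x: _linear_fit(x)[0],
    "linear_r2": lambda x: _linear_fit(x)[1],
    "longest_strike_above_mean": lambda x: float(_longest_run(x > x.mean())),
    "longest_strike_below_mean": lambda x: float(_longest_run(x < x.mean())),
    "sample_entropy": _sample_entropy,
}

CATALOGUE_SIZE: int = len(CATALOGUE)


def extract_catalogue(cset: ChannelSet) -> FeatureVector:
    """Compute the full catalogue on every channel and concatenate.

    Deterministic; features are named ``<channel>__<descriptor>``.
    Non-finite values (undefined ratios on degenerate channels) map to 0
    with a logged warning, keeping the design matrix dense.
    """
    if not cset.channels:
        raise EmptyInputError("channel set is empty")
    names, vals, prov = [], [], []
    for ch in cset:
        x = np.asarray(ch.values, dtype=float)
        if len(x) < 2:
            raise EmptyInputError(f"channel {ch.name!r} has < 2 frames")
        for desc, fn in CATALOGUE.items():
            v = fn(x)
            if not np.isfinite(v):
                logger.warning("feature %s__%s non-finite; mapped to 0",
                               ch.name, desc)
                v = 0.0
            names.append(f"{ch.name}__{desc}")
            vals.append(v)
            prov.append((ch.name, ch.category, desc))
    values = pd.Series(vals, index=names, dtype=float)
    provenance = pd.DataFrame(prov, index=names,
                              columns=["channel", "category", "descriptor"])
    return FeatureVector(values, provenance)


# ---------------------------------------------------------------------------
# Random convolutional kernel transform
# ---------------------------------------------------------------------------

KERNEL_LENGTHS: tuple[int, ...] = (7, 9, 11)


@dataclass(frozen=True)
class KernelSpec:
    """One random convolutional kernel."""

    weights: np.ndarray
    bias: float
    dilation: int
    padding: bool

    def __post_init__(self) -> None:
        object.__setattr__(self, "weights", np.asarray(self.weights, float))
        if len(self.weights) < 2:
            raise InvalidArgumentError("kernel needs at least 2 weights")
        if self.dilation < 1:
            raise InvalidArgumentError("dilation must be >= 1")
        if not np.all(np.isfinite(self.weights)):
            raise InvalidArgumentError("kernel weights must be finite")

    @property
    def length(self) -> int:
        return len(self.weights)

    @property
    def receptive_field(self) -> int:
        return (self.length - 1) * self.dilation + 1


@dataclass
class KernelTransformConfig:
    """Configuration of the kernel transform."""

    n_kernels: int = 10_000
    crop_length: int = 400
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_kernels < 1:
            raise InvalidArgumentError("n_kernels must be >= 1")
        if self.crop_length < max(KERNEL_LENGTHS):
            raise InvalidArgumentError(
                f"crop_length must be >= {max(KERNEL_LENGTHS)}")


def crop_fixed_length(cset: ChannelSet, length: int = 400) -> ChannelSet:
    """Truncate every channel to its first ``length`` values.

    Shorter channels are right-padded by repeating their last value; the
    returned set records the padded frame count in ``padded_frames`` and the
    event is logged.
    """
    out = []
    padded = 0
    for ch in cset:
        x = ch.values
        if len(x) >= length:
            x = x[:length]
        else:
            pad = length - len(x)
            padded = max(padded, pad)
            x = np.concatenate([x, np.full(pad, x[-1])])
        out.append(replace(ch, values=x))
    result = ChannelSet(out)
    result.padded_frames = padded
    if padded:
        logger.warning("channels shorter than %d frames: last value repeated "
                       "%d time(s)", length, padded)
    return result


def sample_kernels(config: KernelTransformConfig,
                   input_length: int | None = None) -> list[KernelSpec]:
    """Draw ``n_kernels`` random kernels, reproducibly under ``config.seed``.

    Sampling law: length uniform on {7, 9, 11}; weights standard normal then
    mean-centred; bias uniform on [-1, 1]; dilation ``2**a`` with ``a``
    uniform on [0, log2((L-1)/(length-1))]; padding with probability 1/2.
    """
    L = config.crop_length if input_length is None else input_length
    if L < max(KERNEL_LENGTHS):
        raise InvalidArgumentError(
            f"input length {L} is below the minimal receptive field")
    rng = np.random.default_rng(config.seed)
    kernels = []
    for _ in range(config.n_kernels):
        length = int(rng.choice(KERNEL_LENGTHS))
        weights = rng.normal(0.0, 1.0, size=length)
        weights -= weights.mean()
        bias = float(rng.uniform(-1.0, 1.0))
        a_max = math.log2((L - 1) / (length - 1))
        dilation = int(2 ** rng.uniform(0.0, a_max))
        padding = bool(rng.random() < 0.5)
        kernels.append(KernelSpec(weights, bias, dilation, padding))
    return kernels


def _convolve(x: np.ndarray, k: KernelSpec) -> np.ndarray:
    """Dilated 1-D convolution with bias; 'valid' output, optional padding."""
    if k.padding:
        pad = ((k.length - 1) // 2) * k.dilation
        x = np.concatenate([np.zeros(pad), x, np.zeros(pad)])
    n_out = len(x) - (k.length - 1) * k.dilation
    if n_out < 1:
        return np.array([k.bias + 0.0])  # receptive field exceeds series
    out = np.full(n_out, k.bias)
    for j, w in enumerate(k.weights):
        out += w * x[j * k.dilation: j * k.dilation + n_out]
    return out


def apply_kernels(cset: ChannelSet, kernels: list[KernelSpec]) -> FeatureVector:
    """Apply kernels to every channel; two features per kernel per channel.

    Per activation map: its maximum and the proportion of positive values
    (PPV, in [0, 1]).  Features are named
    ``<channel>__k<index>_{max,ppv}``, keeping per-channel provenance.
    """
    if not cset.channels:
        raise EmptyInputError("channel set is empty")
    names, vals, prov = [], [], []
    for ch in cset:
        x = np.asarray(ch.values, dtype=float)
        for i, k in enumerate(kernels):
            act = _convolve(x, k)
            names.append(f"{ch.name}__k{i:05d}_max")
            vals.append(float(act.max()))
            prov.append((ch.name, ch.category, f"k{i:05d}_max"))
            names.append(f"{ch.name}__k{i:05d}_ppv")
            vals.append(float(np.mean(act > 0)))
            prov.append((ch.name, ch.category, f"k{i:05d}_ppv"))
    values = pd.Series(vals, index=names, dtype=float)
    provenance = pd.DataFrame(prov, index=names,
                              columns=["channel", "category", "descriptor"])
    return FeatureVector(values, provenance)


# ---------------------------------------------------------------------------
# sklearn-style transformers
# ---------------------------------------------------------------------------


class CatalogueFeaturizer(TransformerMixin, BaseEstimator):
    """Stateless transformer: list of ChannelSets -> catalogue feature table."""

    def fit(self, X, y=None):
        self.n_features_in_ = len(X)
        return self

    def transform(self, X) -> pd.DataFrame:
        fvs = [extract_catalogue(cset) for cset in X]
        self.provenance_ = fvs[0].provenance
        return pd.DataFrame([fv.values for fv in fvs]).reset_index(drop=True)


class RocketFeaturizer(TransformerMixin, BaseEstimator):
    """Kernel-transform transformer: fit samples kernels, transform applies.

    Parameters mirror :class:`KernelTransformConfig`; channels are cropped
    (or last-value padded) to ``crop_length`` before convolution.
    """

    def __init__(self, n_kernels: int = 10_000, crop_length: int = 400,
                 seed: int = 0):
        self.n_kernels = n_kernels
        self.crop_length = crop_length
        self.seed = seed

    def fit(self, X, y=None):
        config = KernelTransformConfig(self.n_kernels, self.crop_length,
                                       self.seed)
        self.kernels_ = sample_kernels(config)
        return self

    def transform(self, X) -> pd.DataFrame:
        if not hasattr(self, "kernels_"):
            raise SchemaError("RocketFeaturizer is not fitted")
        fvs = [apply_kernels(crop_fixed_length(cset, self.crop_length),
                             self.kernels_) for cset in X]
        self.provenance_ = fvs[0].provenance
        return pd.DataFrame([fv.values for fv in fvs]).reset_index(drop=True)
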