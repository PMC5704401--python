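"""Phase-space reconstruction from a scalar observable.

A scalar series ``U_i`` (e.g. a Cα RMSD trace from an MD trajectory) is lifted
to an m-dimensional state trajectory by the method of time delays,

    S_i = (U_i, U_{i+d}, ..., U_{i+(m-1)d}),

where the delay ``d`` is chosen at the first local minimum of the
auto-mutual-information function and the embedding dimension ``m`` by the
false-nearest-neighbors criterion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "ScalarSeries",
    "EmbeddingParams",
    "StateTrajectory",
    "LagProfile",
    "SelectionResult",
    "auto_mutual_information",
    "select_delay",
    "false_nearest_neighbors",
    "select_embedding_dim",
    "delay_embed",
    "estimate_embedding",
]


class DegenerateSeriesError(ValueError):
    """Raised when a series is constant (entropy/variance based steps undefined)."""


@dataclass(frozen=True)
class ScalarSeries:
    """A uniformly sampled scalar observable.

    Parameters
    ----------
    values
        The observations, in observable units (e.g. Å for an RMSD trace).
    dt
        Time between consecutive samples, in time units. Optional metadata;
        sample indices are the primary coordinate.
    label
        Free-text description.
    """

    values: np.ndarray
    dt: float | None = None
    label: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1:
            raise ValueError("series values must be one-dimensional")
        if v.size < 2:
            raise ValueError("series must contain at least 2 values")
        if not np.all(np.isfinite(v)):
            raise ValueError("series contains non-finite values")
        if self.dt is not None and not self.dt > 0:
            raise ValueError("dt must be positive")
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class EmbeddingParams:
    """Delay-embedding parameters: dimension ``m`` and delay ``d`` (in samples)."""

    m: int
    d: int

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("embedding dimension m must be >= 1")
        if self.d < 1:
            raise ValueError("delay d must be >= 1")

    @property
    def span(self) -> int:
        """Number of source samples covered by one state vector minus one."""
        return (self.m - 1) * self.d


@dataclass(frozen=True)
class StateTrajectory:
    """Embedded state vectors, one per row of ``states``."""

    states: np.ndarray
    params: EmbeddingParams
    source_length: int

    def __post_init__(self) -> None:
        expected = self.source_length - self.params.span
        if self.states.shape != (expected, self.params.m):
            raise ValueError(
                f"state array shape {self.states.shape} inconsistent with "
                f"source length {self.source_length} and params {self.params}"
            )
        if expected < 2:
            raise ValueError("trajectory must contain at least 2 states")

    def __len__(self) -> int:
        return self.states.shape[0]


@dataclass(frozen=True)
class LagProfile:
    """Score per lag (mutual information) or per candidate dimension (FNN)."""

    lags: np.ndarray
    scores: np.ndarray
    kind: str = "ami"  # "ami" | "fnn"

    def __post_init__(self) -> None:
        if self.lags.shape != self.scores.shape:
            raise ValueError("lags and scores must have equal length")
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("profile scores must be finite")
        if self.kind == "fnn" and (np.any(self.scores < 0) or np.any(self.scores > 1)):
            raise ValueError("FNN fractions must lie in [0, 1]")


@dataclass(frozen=True)
class SelectionResult:
    """An integer selection plus a convergence flag."""

    value: int
    converged: bool = True

    def __int__(self) -> int:
        return self.value


def _mutual_information_bits(x: np.ndarray, y: np.ndarray, edges: np.ndarray) -> float:
    """Histogram-estimated MI between two equally long samples, in bits."""
    joint, _, _ = np.histogram2d(x, y, bins=[edges, edges])
    joint /= joint.sum()
    px = joint.sum(axis=1)
    py = joint.sum(axis=0)
    nz = joint > 0
    outer = np.outer(px, py)
    return float(np.sum(joint[nz] * np.log2(joint[nz] / outer[nz])))


def auto_mutual_information(
    series: ScalarSeries, max_lag: int, n_bins: int = 16
) -> LagProfile:
    """Mutual information between the series and its lag-τ copy, τ = 0..max_lag.

    Uses an equal-width histogram over the full series range (shared bin edges
    for every lag), with MI reported in bits. ``I(0)`` is the entropy of the
    binned series and bounds the profile from above.
    """
    v = series.values
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if max_lag >= len(v) - 1:
        raise ValueError(
            f"max_lag={max_lag} too large for series of length {len(v)} "
            f"(need max_lag < n - 1)"
        )
    lo, hi = float(v.min()), float(v.max())
    if lo == hi:
        raise DegenerateSeriesError("constant series: mutual information undefined")
    edges = np.linspace(lo, hi, n_bins + 1)
    edges[-1] = np.nextafter(edges[-1], np.inf)  # include the max in the top bin
    scores = np.empty(max_lag + 1)
    for tau in range(max_lag + 1):
        x = v[: len(v) - tau]
        y = v[tau:]
        scores[tau] = _mutual_information_bits(x, y, edges)
    return LagProfile(lags=np.arange(max_lag + 1), scores=scores, kind="ami")


def select_delay(profile: LagProfile) -> SelectionResult:
    """First local minimum of the lag profile.

    Returns the smallest τ ≥ 1 with ``score(τ) < score(τ-1)`` and
    ``score(τ) <= score(τ+1)`` — a plateau counts as a minimum at its first
    lag. If no interior minimum exists the largest lag is returned with
    ``converged=False``.
    """
    s = profile.scores
    if len(s) < 3:
        raise ValueError("profile must contain at least 3 lags")
    for tau in range(1, len(s) - 1):
        if s[tau] < s[tau - 1] and s[tau] <= s[tau + 1]:
            return SelectionResult(int(profile.lags[tau]), converged=True)
    return SelectionResult(int(profile.lags[-1]), converged=False)


def false_nearest_neighbors(
    series: ScalarSeries,
    d: int,
    max_dim: int,
    rtol: float = 10.0,
    atol: float = 2.0,
) -> LagProfile:
    """Fraction of false nearest neighbors per candidate dimension m = 1..max_dim.

    For each m, every embedded point's nearest neighbor (maximum norm,
    self excluded) is lifted to dimension m+1; the neighbor is false when the
    extra-coordinate separation exceeds ``rtol`` times the m-dimensional
    distance, or the lifted distance exceeds ``atol`` standard deviations of
    the series. If the series is too short to lift at some m, the profile is
    truncated at the last computable dimension.
    """
    v = series.values
    sigma = float(np.std(v))
    if sigma == 0.0:
        raise DegenerateSeriesError("constant series: FNN undefined")
    dims, fracs = [], []
    for m in range(1, max_dim + 1):
        n_lift = len(v) - m * d  # points embeddable at m+1
        if n_lift < 2:
            break
        emb = delay_embed_array(v, m, d)[:n_lift]
        extra = v[m * d : m * d + n_lift]
        tree = cKDTree(emb)
        dist, idx = tree.query(emb, k=2, p=np.inf)
        nn_dist, nn_idx = dist[:, 1], idx[:, 1]
        lift_sep = np.abs(extra - extra[nn_idx])
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(nn_dist > 0, lift_sep / nn_dist, np.inf)
        ratio[(nn_dist == 0) & (lift_sep == 0)] = 0.0
        lifted = np.maximum(nn_dist, lift_sep)
        false = (ratio > rtol) | (lifted > atol * sigma)
        dims.append(m)
        fracs.append(float(np.mean(false)))
    if not dims:
        raise ValueError(
            f"series of length {len(v)} too short for FNN at any m with delay {d}"
        )
    return LagProfile(lags=np.array(dims), scores=np.array(fracs), kind="fnn")


def select_embedding_dim(profile: LagProfile, threshold: float = 0.01) -> SelectionResult:
    """Smallest m whose FNN fraction drops to ``threshold`` or below."""
    if len(profile.scores) == 0:
        raise ValueError("empty FNN profile")
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    below = np.nonzero(profile.scores <= threshold)[0]
    if below.size:
        return SelectionResult(int(profile.lags[below[0]]), converged=True)
    return SelectionResult(int(profile.lags[-1]), converged=False)


def delay_embed_array(values: np.ndarray, m: int, d: int) -> np.ndarray:
    """Raw delay embedding of a 1-D array; rows are states, columns lags."""
    n_states = len(values) - (m - 1) * d
    if n_states < 2:
        raise ValueError(
            f"series of length {len(values)} too short to embed at m={m}, d={d}: "
            f"need at least {(m - 1) * d + 2} samples"
        )
    return np.stack([values[k * d : k * d + n_states] for k in range(m)], axis=1)


def delay_embed(series: ScalarSeries, params: EmbeddingParams) -> StateTrajectory:
    """Delay-embed a scalar series into an m-dimensional state trajectory.

    Produces exactly ``n - (m-1)·d`` states; component k of state i is the
    source value at index ``i + k·d``.
    """
    states = delay_embed_array(series.values, params.m, params.d)
    return StateTrajectory(states=states, params=params, source_length=len(series))


def estimate_embedding(
    series: ScalarSeries,
    max_lag: int = 200,
    max_dim: int = 12,
    n_bins: int = 16,
    rtol: float = 10.0,
    atol: float = 2.0,
    fnn_threshold: float = 0.01,
) -> tuple[EmbeddingParams, dict]:
    """AMI-then-FNN parameter selection on the full series.

    Returns the chosen ``EmbeddingParams`` plus a diagnostics dict holding both
    profiles and convergence flags. The parameters are meant to be estimated
    once on the whole series and reused for every analysis window.
    """
    ami = auto_mutual_information(series, max_lag=max_lag, n_bins=n_bins)
    d_sel = select_delay(ami)
    fnn = false_nearest_neighbors(series, d=d_sel.value, max_dim=max_dim, rtol=rtol, atol=atol)
    m_sel = select_embedding_dim(fnn, threshold=fnn_threshold)
    params = EmbeddingParams(m=m_sel.value, d=d_sel.value)
    diag = {
        "ami_profile": ami,
        "fnn_profile": fnn,
        "delay_converged": d_sel.converged,
        "dim_converged": m_sel.converged,
    }
    return params, diag
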