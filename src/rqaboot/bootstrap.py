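"""Bootstrap confidence bands for windowed DET/LAM and transition flagging.

All windows' line-length distributions are pooled into one global
distribution, taken to describe the system's baseline recurrence structure.
Bootstrap replicates are drawn from it — each replicate resamples
``round(mean structures per window)`` individual line lengths (singletons
included) with replacement — and the measure (DET or LAM) is computed per
replicate. The empirical central quantiles of the replicate distribution give
the lower/upper confidence levels; windows whose measure falls strictly
outside the band are flagged as transition regions, i.e. departures from the
baseline recurrence dynamics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .rqa import LineDistribution
from .windows import WindowResult

__all__ = [
    "GlobalDistribution",
    "BootstrapBand",
    "TransitionReport",
    "pool_distributions",
    "bootstrap_measure",
    "flag_transitions",
    "report_to_json",
]


@dataclass(frozen=True)
class GlobalDistribution:
    """Pooled line-length counts over all windows."""

    kind: str
    counts: dict[int, int]
    n_windows: int
    mean_structures_per_window: float

    @property
    def total_structures(self) -> int:
        return sum(self.counts.values())

    def pooled_measure(self, lmin: int = 2) -> float:
        """The measure (DET/LAM form) computed on the pooled counts directly."""
        denom = sum(l * c for l, c in self.counts.items())
        if denom == 0:
            return 0.0
        return sum(l * c for l, c in self.counts.items() if l >= lmin) / denom


@dataclass(frozen=True)
class BootstrapBand:
    """Bootstrap replicate values of a measure plus the central confidence band."""

    samples: np.ndarray
    lower: float
    upper: float
    alpha: float
    draw_size: int
    seed: int

    @property
    def n_boot(self) -> int:
        return self.samples.size

    def fraction_inside(self) -> float:
        """Fraction of replicates inside [lower, upper] (inclusive)."""
        return float(
            np.mean((self.samples >= self.lower) & (self.samples <= self.upper))
        )


@dataclass(frozen=True)
class TransitionReport:
    """Maximal runs of windows above/below the confidence band, in time units."""

    measure: str
    regions_above: list[tuple[float, float]]
    regions_below: list[tuple[float, float]]


def pool_distributions(dists: list[LineDistribution]) -> GlobalDistribution:
    """Merge per-window line distributions into one global distribution.

    The mean number of structures per window (over all lengths >= 1) sets the
    bootstrap draw size.
    """
    if not dists:
        raise ValueError("cannot pool an empty list of distributions")
    kinds = {d.kind for d in dists}
    if len(kinds) > 1:
        raise ValueError(f"cannot pool mixed line kinds: {sorted(kinds)}")
    merged: dict[int, int] = {}
    for d in dists:
        for length, c in d.counts.items():
            merged[length] = merged.get(length, 0) + c
    mean = sum(d.total_structures for d in dists) / len(dists)
    return GlobalDistribution(
        kind=kinds.pop(),
        counts=merged,
        n_windows=len(dists),
        mean_structures_per_window=mean,
    )


def _type1_quantile(sorted_samples: np.ndarray, p: float) -> float:
    """Inverse empirical CDF (type-1) quantile of pre-sorted samples."""
    n = sorted_samples.size
    idx = max(int(np.ceil(n * p)) - 1, 0)
    return float(sorted_samples[idx])


def bootstrap_measure(
    global_dist: GlobalDistribution,
    n_boot: int = 1000,
    lmin: int = 2,
    alpha: float = 0.95,
    seed: int = 0,
    draw_size: int | None = None,
) -> BootstrapBand:
    """Bootstrap the global line distribution into a confidence band.

    Each replicate draws ``round(mean_structures_per_window)`` line lengths
    with replacement (probability proportional to the pooled counts) and
    evaluates Σ_{l≥lmin} l / Σ l on the drawn multiset. The band is the
    central (1−alpha)/2 … 1−(1−alpha)/2 pair of type-1 empirical quantiles.
    Replicates are fully determined by ``seed``.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if global_dist.total_structures == 0:
        raise ValueError("global distribution is empty")
    if draw_size is None:
        draw_size = int(round(global_dist.mean_structures_per_window))
    if draw_size < 1:
        raise ValueError("draw size must be >= 1")
    lengths = np.array(sorted(global_dist.counts), dtype=np.int64)
    weights = np.array([global_dist.counts[l] for l in lengths], dtype=float)
    probs = weights / weights.sum()
    rng = np.random.default_rng(seed)
    draws = rng.choice(lengths, size=(n_boot, draw_size), replace=True, p=probs)
    totals = draws.sum(axis=1).astype(float)
    kept = np.where(draws >= lmin, draws, 0).sum(axis=1).astype(float)
    samples = np.divide(kept, totals, out=np.zeros(n_boot), where=totals > 0)
    s = np.sort(samples)
    lo_p = (1.0 - alpha) / 2.0
    lower = _type1_quantile(s, lo_p)
    upper = _type1_quantile(s, 1.0 - lo_p)
    return BootstrapBand(
        samples=samples,
        lower=lower,
        upper=upper,
        alpha=alpha,
        draw_size=draw_size,
        seed=seed,
    )


def flag_transitions(
    results: list[WindowResult], band: BootstrapBand, measure: str = "det"
) -> TransitionReport:
    """Maximal runs of windows strictly above/below the band, as time regions.

    Each region is reported as [first window start time, last window start
    time]; note every window extends one window-width into the future of its
    start.
    """
    if measure not in ("det", "lam"):
        raise ValueError("measure must be 'det' or 'lam'")
    values = [getattr(r.measures, measure) for r in results]
    times = [r.start_time for r in results]

    def runs(flags: list[bool]) -> list[tuple[float, float]]:
        out = []
        start = None
        for i, f in enumerate(flags):
            if f and start is None:
                start = i
            elif not f and start is not None:
                out.append((times[start], times[i - 1]))
                start = None
        if start is not None:
            out.append((times[start], times[-1]))
        return out

    above = runs([v > band.upper for v in values])
    below = runs([v < band.lower for v in values])
    return TransitionReport(measure=measure, regions_above=above, regions_below=below)


def report_to_json(
    report: TransitionReport, band: BootstrapBand, n_boot: int | None = None
) -> str:
    """Serialize a band + transition report as a JSON document."""
    payload = {
        "measure": report.measure,
        "lower": band.lower,
        "upper": band.upper,
        "alpha": band.alpha,
        "n_boot": band.n_boot if n_boot is None else n_boot,
        "draw_size": band.draw_size,
        "seed": band.seed,
        "regions_above": [list(r) for r in report.regions_above],
        "regions_below": [list(r) for r in report.regions_below],
    }
    return json.dumps(payload, indent=2, sort_keys=True)
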