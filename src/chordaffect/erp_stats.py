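"""Global field power, data-driven window selection, and cluster-based
permutation contrasts across electrodes.

The channel-level statistic is a Wilcoxon signed-rank z on paired
per-subject condition differences; clusters are connected components of
suprathreshold channels under a spatial adjacency graph, summarised by
their mass (sum of |z|), with FWER control from the permutation
distribution of the maximum cluster mass under per-subject condition
swaps (sign flips).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .preprocess import EpochSet

__all__ = [
    "GFPCurve",
    "ClusterResult",
    "grand_average",
    "gfp_curve",
    "select_windows",
    "window_mean_map",
    "signed_rank_z",
    "cluster_permutation",
]


@dataclass(frozen=True)
class GFPCurve:
    times_ms: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.values < 0):
            raise ValueError("GFP must be non-negative")


@dataclass(frozen=True)
class ClusterResult:
    channels: tuple[str, ...]
    mass: float
    p_value: float
    sign: int                 # +1 for A > B clusters, -1 for A < B
    contrast: str = ""
    window_ms: tuple[float, float] | None = None
    n_permutations: int = 0


def grand_average(epochs: EpochSet, condition: str | None = None) -> np.ndarray:
    """Mean over trials (channels x time); optionally restricted to one condition."""
    if condition is None:
        sel = np.ones(epochs.n_trials, dtype=bool)
    else:
        sel = np.asarray([c == condition for c in epochs.conditions])
    if not sel.any():
        raise ValueError(f"no trials of condition {condition!r}")
    return epochs.data[sel].mean(axis=0)


def gfp_curve(avg: np.ndarray, times_ms: np.ndarray) -> GFPCurve:
    """Spatial standard deviation across channels at each time point."""
    if avg.ndim != 2 or avg.shape[0] < 2:
        raise ValueError("need a (channels x time) array with >= 2 channels")
    return GFPCurve(times_ms=np.asarray(times_ms), values=avg.std(axis=0, ddof=0))


def select_windows(
    curve: GFPCurve,
    n_peaks: int = 3,
    half_width_ms: float = 10.0,
) -> list[tuple[float, float]]:
    """Windows (peak +/- half width) around the most prominent GFP maxima.

    Only post-stimulus local maxima are considered; peaks are ranked by
    prominence, ties broken in favour of the earlier latency.  Windows are
    returned sorted by latency.  Fewer maxima than requested yields a
    warning and a shorter list.
    """
    if n_peaks < 1:
        raise ValueError("n_peaks must be >= 1")
    post = curve.times_ms > 0
    values = curve.values[post]
    times = curve.times_ms[post]
    peaks, props = _find_peaks(values)
    if len(peaks) == 0:
        warnings.warn("GFP curve has no post-stimulus local maxima")
        return []
    order = sorted(range(len(peaks)), key=lambda i: (-props[i], times[peaks[i]]))
    chosen = sorted(times[peaks[i]] for i in order[:n_peaks])
    if len(chosen) < n_peaks:
        warnings.warn(
            f"only {len(chosen)} GFP maxima found, {n_peaks} requested"
        )
    return [(t - half_width_ms, t + half_width_ms) for t in chosen]


def _find_peaks(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    from scipy.signal import find_peaks as _fp

    peaks, props = _fp(values, prominence=0.0)
    return peaks, props["prominences"]


def window_mean_map(
    epochs: EpochSet, condition: str, window_ms: tuple[float, float]
) -> np.ndarray:
    """Per-channel mean over trials of a condition and a time window."""
    avg = grand_average(epochs, condition)
    mask = (epochs.times_ms >= window_ms[0]) & (epochs.times_ms <= window_ms[1])
    if not mask.any():
        raise ValueError(f"window {window_ms} outside the epoch time axis")
    return avg[:, mask].mean(axis=1)


def signed_rank_z(diffs: np.ndarray) -> np.ndarray:
    """Vectorised large-sample Wilcoxon signed-rank z per column.

    ``diffs`` is (n_subjects, n_channels).  Mid-ranks of |d| handle ties;
    zero differences contribute neither signal nor variance.
    """
    diffs = np.atleast_2d(np.asarray(diffs, dtype=float))
    absd = np.abs(diffs)
    ranks = stats.rankdata(absd, axis=0)
    ranks = np.where(absd == 0, 0.0, ranks)
    t = np.sum(np.sign(diffs) * ranks, axis=0)
    var = np.sum(ranks**2, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(var > 0, t / np.sqrt(np.maximum(var, 1e-300)), 0.0)
    return z


def _components(mask: np.ndarray, neighbours: list[np.ndarray]) -> list[list[int]]:
    """Connected components of True channels under the adjacency graph."""
    seen = np.zeros(len(mask), dtype=bool)
    comps = []
    for start in np.flatnonzero(mask):
        if seen[start]:
            continue
        stack, comp = [start], []
        seen[start] = True
        while stack:
            i = stack.pop()
            comp.append(i)
            for j in neighbours[i]:
                if mask[j] and not seen[j]:
                    seen[j] = True
                    stack.append(j)
        comps.append(comp)
    return comps


def _max_cluster_mass(
    z: np.ndarray, z_crit: float, neighbours: list[np.ndarray]
) -> float:
    best = 0.0
    for sgn in (1.0, -1.0):
        for comp in _components(sgn * z > z_crit, neighbours):
            best = max(best, float(np.sum(np.abs(z[comp]))))
    return best


def cluster_permutation(
    maps_a: np.ndarray,
    maps_b: np.ndarray,
    adjacency: np.ndarray,
    channel_names: tuple[str, ...] | None = None,
    n_perm: int = 800,
    alpha: float = 0.05,
    cluster_alpha: float = 0.05,
    seed=0,
    contrast: str = "",
    window_ms: tuple[float, float] | None = None,
) -> list[ClusterResult]:
    """Paired cluster-based permutation contrast between two condition maps.

    ``maps_a``/``maps_b`` are (n_subjects, n_channels) window-mean maps.
    Returns every observed cluster with its FWER-corrected p-value
    ``(1 + #{null >= mass}) / (1 + n_perm)``; callers filter at ``alpha``.
    """
    maps_a = np.asarray(maps_a, dtype=float)
    maps_b = np.asarray(maps_b, dtype=float)
    if maps_a.shape != maps_b.shape:
        raise ValueError("condition maps must have identical shapes")
    n_sub, n_chan = maps_a.shape
    if n_sub < 6:
        raise ValueError("need at least 6 subjects for the signed-rank statistic")
    adjacency = np.asarray(adjacency, dtype=bool)
    if adjacency.shape != (n_chan, n_chan):
        raise ValueError("adjacency must be (n_channels, n_channels)")
    neighbours = [np.flatnonzero(adjacency[i]) for i in range(n_chan)]
    if _graph_disconnected(neighbours, n_chan):
        warnings.warn("channel adjacency graph is disconnected")

    diffs = maps_a - maps_b
    absd = np.abs(diffs)
    ranks = stats.rankdata(absd, axis=0)
    ranks = np.where(absd == 0, 0.0, ranks)
    signed_ranks = np.sign(diffs) * ranks
    var = np.sum(ranks**2, axis=0)
    denom = np.sqrt(np.maximum(var, 1e-300))
    z_obs = np.where(var > 0, signed_ranks.sum(axis=0) / denom, 0.0)
    z_crit = stats.norm.ppf(1.0 - cluster_alpha / 2.0)

    # per-subject condition swaps flip the sign of the whole difference
    # map; |d| and hence the ranks are unchanged, so every permutation's
    # z-map is a single sign-matrix product
    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(n_perm, n_sub))
    z_perm = np.where(var > 0, (signs @ signed_ranks) / denom, 0.0)
    null = np.array(
        [_max_cluster_mass(z_perm[p], z_crit, neighbours) for p in range(n_perm)]
    )

    names = channel_names or tuple(f"ch{i}" for i in range(n_chan))
    results = []
    for sgn in (1, -1):
        for comp in _components(sgn * z_obs > z_crit, neighbours):
            mass = float(np.sum(np.abs(z_obs[comp])))
            p = float((1 + np.sum(null >= mass)) / (1 + n_perm))
            results.append(
                ClusterResult(
                    channels=tuple(names[i] for i in sorted(comp)),
                    mass=mass,
                    p_value=p,
                    sign=sgn,
                    contrast=contrast,
                    window_ms=window_ms,
                    n_permutations=n_perm,
                )
            )
    results.sort(key=lambda r: r.p_value)
    return results


def _graph_disconnected(neighbours: list[np.ndarray], n: int) -> bool:
    if n == 0:
        return False
    seen = np.zeros(n, dtype=bool)
    stack = [0]
    seen[0] = True
    while stack:
        i = stack.pop()
        for j in neighbours[i]:
            if not seen[j]:
                seen[j] = True
                stack.append(j)
    return not seen.all()
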