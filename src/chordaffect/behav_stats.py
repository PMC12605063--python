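"""Behavioural statistics: stimulus x response association, rank-based
reaction-time comparisons, and Bonferroni-corrected post-hocs.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

__all__ = [
    "ContingencyTable",
    "contingency_from_trials",
    "rt_groups_from_trials",
    "fisher_exact",
    "kruskal_wallis",
    "pairwise_wilcoxon_bonferroni",
    "behaviour_report",
]

STIMULUS_TYPES = ("consonant", "dissonant", "neutral")
RESPONSE_CATEGORIES = ("pleasant", "unpleasant", "neutral")


@dataclass(frozen=True)
class ContingencyTable:
    counts: np.ndarray
    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("counts shape does not match labels")
        if np.any(c < 0) or not np.issubdtype(c.dtype, np.integer):
            raise ValueError("counts must be non-negative integers")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def contingency_from_trials(trials: pd.DataFrame) -> ContingencyTable:
    counts = np.zeros((len(STIMULUS_TYPES), len(RESPONSE_CATEGORIES)), dtype=int)
    for i, st in enumerate(STIMULUS_TYPES):
        sub = trials[trials["stimulus_type"] == st]
        for j, resp in enumerate(RESPONSE_CATEGORIES):
            counts[i, j] = int((sub["response"] == resp).sum())
    return ContingencyTable(counts, STIMULUS_TYPES, RESPONSE_CATEGORIES)


def rt_groups_from_trials(trials: pd.DataFrame) -> dict[str, np.ndarray]:
    """Six RT samples keyed by '<type>_<congruent|incongruent>'."""
    groups = {}
    for st in STIMULUS_TYPES:
        for flag, tag in ((True, "congruent"), (False, "incongruent")):
            sel = (trials["stimulus_type"] == st) & (trials["congruent"] == flag)
            groups[f"{st}_{tag}"] = trials.loc[sel, "rt_ms"].to_numpy(dtype=float)
    return groups


def _table_log_prob(tables: np.ndarray, row_m: np.ndarray, col_m: np.ndarray) -> np.ndarray:
    """Log multivariate-hypergeometric probability of fixed-margin tables."""
    n = row_m.sum()
    const = gammaln(row_m + 1).sum() + gammaln(col_m + 1).sum() - gammaln(n + 1)
    cells = gammaln(np.asarray(tables) + 1).sum(axis=(-2, -1))
    return const - cells


def fisher_exact(
    table: ContingencyTable, n_sim: int = 100_000, seed=0
) -> float:
    """Two-sided Fisher test of independence.

    2x2 tables use the exact hypergeometric p (summing the probabilities
    of all fixed-margin tables no more likely than the observed one).
    Larger tables use a Monte-Carlo p over fixed-margin tables with the
    add-one correction (1 + #extreme) / (1 + n_sim).
    """
    counts = np.asarray(table.counts, dtype=np.int64)
    if counts.sum() == 0:
        raise ValueError("empty contingency table")
    if counts.shape == (2, 2):
        return float(stats.fisher_exact(counts, alternative="two-sided")[1])
    if n_sim < 10_000:
        raise ValueError("use at least 10^4 simulations for r x c tables")
    row_m = counts.sum(axis=1)
    col_m = counts.sum(axis=0)
    obs_lp = _table_log_prob(counts, row_m, col_m)
    rng = np.random.default_rng(seed)
    sampler = stats.random_table(row_m, col_m)
    sampled = sampler.rvs(size=n_sim, random_state=rng)
    lp = _table_log_prob(sampled, row_m, col_m)
    extreme = int(np.sum(lp <= obs_lp + 1e-9))
    return float((1 + extreme) / (1 + n_sim))


def kruskal_wallis(groups: dict[str, np.ndarray]) -> tuple[float, int, float]:
    """Tie-corrected Kruskal-Wallis H with chi-square p on k-1 df."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = []
    for name, g in groups.items():
        g = np.asarray(g, dtype=float)
        if g.size == 0:
            raise ValueError(f"group {name!r} is empty")
        arrays.append(g)
    if np.ptp(np.concatenate(arrays)) == 0:
        # all observations identical: H is 0 by convention
        return 0.0, len(arrays) - 1, 1.0
    h, p = stats.kruskal(*arrays)
    return float(h), len(arrays) - 1, float(p)


def pairwise_wilcoxon_bonferroni(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    """All unordered pairwise two-sided rank-sum tests, Bonferroni adjusted.

    The multiplier is the number of pairs actually tested (15 for six
    groups); adjusted p = min(1, m * raw p).
    """
    names = list(groups)
    if len(names) < 2:
        raise ValueError("need at least two groups")
    pairs = list(combinations(names, 2))
    m = len(pairs)
    adj = pd.DataFrame(np.ones((len(names), len(names))), index=names, columns=names)
    for a, b in pairs:
        ga, gb = np.asarray(groups[a], float), np.asarray(groups[b], float)
        if ga.size == 0 or gb.size == 0:
            raise ValueError("groups must be non-empty")
        if np.ptp(np.concatenate([ga, gb])) == 0:
            raw = 1.0
        else:
            raw = float(stats.mannwhitneyu(ga, gb, alternative="two-sided")[1])
        p = min(1.0, m * raw)
        adj.loc[a, b] = p
        adj.loc[b, a] = p
    return adj


def behaviour_report(trials: pd.DataFrame, n_sim: int = 100_000, seed=0) -> dict:
    """Association test, RT omnibus and post-hocs in one structured result."""
    table = contingency_from_trials(trials)
    groups = rt_groups_from_trials(trials)
    groups = {k: v for k, v in groups.items() if v.size > 0}
    h, df, p_kw = kruskal_wallis(groups)
    return {
        "contingency": table.counts.tolist(),
        "fisher_p": fisher_exact(table, n_sim=n_sim, seed=seed),
        "kruskal": {"H": h, "df": df, "p": p_kw, "n": int(sum(v.size for v in groups.values()))},
        "rt_means_ms": {k: float(np.mean(v)) for k, v in groups.items()},
        "pairwise_bonferroni": pairwise_wilcoxon_bonferroni(groups).to_dict(),
    }
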