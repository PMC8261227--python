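"""Confidence in inferred ranks via randomized-order repeatability and
split-half agreement.

Sequential ratings depend on the order in which events are processed and on
which events were sampled.  Two resampling diagnostics quantify how much:

* repeatability — shuffle the event order, recompute final Elo ranks, and
  summarize the mean pairwise rank correlation among replicate orderings;
* splitting — randomly split the events in half, rank each half
  independently, and correlate the two half-data rank vectors.

Values near 1 mean the data pin down a stable order; values near 0 mean
the inferred ranks are mostly noise.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats

from .events import EventTable
from .ratings import elo_sequence


@dataclass
class UncertaintyResult:
    method: str  # repeatability | splitting
    correlations: np.ndarray
    mean: float
    ci95: tuple[float, float]
    excluded: list[str]  # individuals dropped from >=1 replicate (splitting)

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "mean": self.mean,
            "ci_lo95": self.ci95[0],
            "ci_hi95": self.ci95[1],
            "n_replicates": len(self.correlations),
        }


def _corr(x: np.ndarray, y: np.ndarray, flavor: str) -> float:
    if np.std(x) == 0 or np.std(y) == 0:
        return np.nan
    if flavor == "spearman":
        return float(stats.spearmanr(x, y).statistic)
    return float(stats.pearsonr(x, y).statistic)


def _summarize(method, cors, excluded) -> UncertaintyResult:
    cors = np.asarray(cors, dtype=float)
    finite = cors[np.isfinite(cors)]
    if len(finite) == 0:
        raise ValueError("no replicate produced a defined correlation")
    lo, hi = np.percentile(finite, [2.5, 97.5])
    return UncertaintyResult(
        method, cors, float(finite.mean()), (float(lo), float(hi)), excluded
    )


def uncertainty_by_repeatability(
    table: EventTable,
    n_reps: int = 10,
    k: float = 100.0,
    start: float = 1000.0,
    seed=None,
    flavor: str = "spearman",
) -> UncertaintyResult:
    """Mean pairwise rank correlation among Elo runs on shuffled event orders.

    Each replicate processes the same events in an independent random
    order; the summary is the mean Spearman correlation over all replicate
    pairs (Pearson with ``flavor='pearson'``).
    """
    if len(table.usable) < 2:
        raise ValueError("need at least 2 usable events")
    rng = np.random.default_rng(seed)
    n_ev = len(table.usable)
    finals = []
    for _ in range(n_reps):
        order = rng.permutation(n_ev)
        _, rr = elo_sequence(table, k=k, start=start, order=order)
        finals.append(rr.scores)
    cors = [
        _corr(finals[a], finals[b], flavor)
        for a, b in combinations(range(n_reps), 2)
    ]
    return _summarize("repeatability", cors, [])


def uncertainty_by_splitting(
    table: EventTable,
    n_reps: int = 10,
    k: float = 100.0,
    start: float = 1000.0,
    seed=None,
    flavor: str = "spearman",
) -> UncertaintyResult:
    """Rank agreement between Elo runs on random halves of the events.

    Per replicate the usable events are split uniformly at random into two
    halves; individuals absent from either half are excluded from that
    replicate's correlation (and reported in ``excluded``).
    """
    ev = table.usable
    n_ev = len(ev)
    if n_ev < 4:
        raise ValueError("need at least 4 usable events to split")
    rng = np.random.default_rng(seed)
    winners = ev["winner"].to_numpy()
    losers = ev["loser"].to_numpy()
    ids = table.ids
    idx_of = {i: k_ for k_, i in enumerate(ids)}
    cors = []
    excluded: set[str] = set()
    for _ in range(n_reps):
        perm = rng.permutation(n_ev)
        halves = (np.sort(perm[: n_ev // 2]), np.sort(perm[n_ev // 2 :]))
        scores, present = [], []
        for half in halves:
            s = _elo_scores(winners[half], losers[half], ids, idx_of, k, start)
            scores.append(s)
            pres = np.zeros(len(ids), dtype=bool)
            for arr in (winners[half], losers[half]):
                for who in arr:
                    pres[idx_of[who]] = True
            present.append(pres)
        both = present[0] & present[1]
        excluded.update(np.array(ids)[~both])
        if both.sum() < 3:
            cors.append(np.nan)
            continue
        cors.append(_corr(scores[0][both], scores[1][both], flavor))
    return _summarize("splitting", cors, sorted(excluded))


def _elo_scores(winners, losers, ids, idx_of, k, start) -> np.ndarray:
    rating = np.full(len(ids), float(start))
    for w, l in zip(winners, losers):
        iw, il = idx_of[w], idx_of[l]
        e = 1.0 / (1.0 + 10.0 ** ((rating[il] - rating[iw]) / 400.0))
        delta = k * (1.0 - e)
        rating[iw] += delta
        rating[il] -= delta
    return rating
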