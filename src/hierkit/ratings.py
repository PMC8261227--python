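"""Sequential rating systems (Elo, Glicko) over chronologically ordered events.

Both systems start every individual at a common rating and update the two
participants after each contest, so early ranks pass through a burn-in
period; full rating trajectories are exposed so users can inspect
convergence.  Glicko additionally tracks a per-individual rating deviation
(RD) quantifying rating uncertainty, and scales updates by the opponent's
RD, so the two participants' gains and losses are not matched.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .events import EventTable

Q_GLICKO = math.log(10.0) / 400.0


@dataclass
class RatingTrajectory:
    """Per-individual rating path: list of (event index, rating) pairs.

    The first entry of every path is (-1, start value).  For Glicko a
    parallel ``rd`` dict holds the rating-deviation path.
    """

    ratings: dict[str, list[tuple[int, float]]]
    rd: dict[str, list[tuple[int, float]]] | None = None

    def final(self) -> dict[str, float]:
        return {i: path[-1][1] for i, path in self.ratings.items()}

    def final_rd(self) -> dict[str, float] | None:
        if self.rd is None:
            return None
        return {i: path[-1][1] for i, path in self.rd.items()}


@dataclass
class RankResult:
    """Scores and integer ranks (1 = highest; average rank on exact ties)."""

    method: str
    ids: list[str]
    scores: np.ndarray
    ranks: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.ranks = stats.rankdata(-self.scores, method="average")

    def score_of(self) -> dict[str, float]:
        return dict(zip(self.ids, self.scores))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"id": self.ids, "method": self.method, "score": self.scores,
             "rank": self.ranks}
        )


def _check_order(table: EventTable, allow_unordered: bool) -> pd.DataFrame:
    ev = table.usable
    if not allow_unordered:
        nights = ev["night"].to_numpy()
        if np.any(np.diff(nights) < 0):
            raise ValueError(
                "events are not chronologically ordered across nights; "
                "pass allow_unordered=True to override"
            )
    return ev


def elo_sequence(
    table: EventTable,
    k: float = 100.0,
    start: float = 1000.0,
    allow_unordered: bool = False,
    order: np.ndarray | None = None,
) -> tuple[RatingTrajectory, RankResult]:
    """Elo ratings updated once per event, in chronological order.

    The winner's expected score is E = 1/(1 + 10^((R_loser - R_winner)/400));
    the winner gains k(1 - E) and the loser loses the same amount, so the
    rating sum is conserved.  ``order`` optionally permutes the event rows
    (used by the rank-uncertainty procedures).
    """
    ev = _check_order(table, allow_unordered or order is not None)
    winners = ev["winner"].to_numpy()
    losers = ev["loser"].to_numpy()
    if order is not None:
        winners, losers = winners[order], losers[order]
    rating = {i: start for i in table.ids}
    traj = {i: [(-1, start)] for i in table.ids}
    for idx, (w, l) in enumerate(zip(winners, losers)):
        rw, rl = rating[w], rating[l]
        e = 1.0 / (1.0 + 10.0 ** ((rl - rw) / 400.0))
        delta = k * (1.0 - e)
        rating[w] = rw + delta
        rating[l] = rl - delta
        traj[w].append((idx, rating[w]))
        traj[l].append((idx, rating[l]))
    ids = table.ids
    scores = np.array([rating[i] for i in ids])
    return RatingTrajectory(traj), RankResult("elo", ids, scores)


def _g(rd: float) -> float:
    return 1.0 / math.sqrt(1.0 + 3.0 * Q_GLICKO**2 * rd**2 / math.pi**2)


def glicko_sequence(
    table: EventTable,
    r0: float = 1500.0,
    rd0: float = 350.0,
    rd_floor: float = 30.0,
    allow_unordered: bool = False,
    order: np.ndarray | None = None,
) -> tuple[RatingTrajectory, RankResult]:
    """Glicko ratings with one rating period per event.

    Single-game update: with g(RD) = 1/sqrt(1 + 3 q^2 RD^2 / pi^2) and
    E = 1/(1 + 10^(-g(RD_opp)(r - r_opp)/400)),
    d^2 = [q^2 g(RD_opp)^2 E(1-E)]^(-1),
    r' = r + q/(1/RD^2 + 1/d^2) * g(RD_opp) (s - E),
    RD' = sqrt(1/(1/RD^2 + 1/d^2)).

    RD shrinks with every game (never exceeds its start value rd0; no
    between-period inflation) and is floored at ``rd_floor`` so ratings
    stay responsive.
    """
    ev = _check_order(table, allow_unordered or order is not None)
    winners = ev["winner"].to_numpy()
    losers = ev["loser"].to_numpy()
    if order is not None:
        winners, losers = winners[order], losers[order]
    rating = {i: r0 for i in table.ids}
    rd = {i: rd0 for i in table.ids}
    traj = {i: [(-1, r0)] for i in table.ids}
    rd_traj = {i: [(-1, rd0)] for i in table.ids}
    q = Q_GLICKO
    for idx, (w, l) in enumerate(zip(winners, losers)):
        updates = {}
        for me, opp, s in ((w, l, 1.0), (l, w, 0.0)):
            g_opp = _g(rd[opp])
            e = 1.0 / (1.0 + 10.0 ** (-g_opp * (rating[me] - rating[opp]) / 400.0))
            d2 = 1.0 / (q**2 * g_opp**2 * e * (1.0 - e))
            denom = 1.0 / rd[me] ** 2 + 1.0 / d2
            r_new = rating[me] + (q / denom) * g_opp * (s - e)
            rd_new = max(math.sqrt(1.0 / denom), rd_floor)
            updates[me] = (r_new, min(rd_new, rd0))
        for me, (r_new, rd_new) in updates.items():
            rating[me], rd[me] = r_new, rd_new
            traj[me].append((idx, r_new))
            rd_traj[me].append((idx, rd_new))
    ids = table.ids
    scores = np.array([rating[i] for i in ids])
    return RatingTrajectory(traj, rd_traj), RankResult("glicko", ids, scores)


def rank_agreement(
    a: RankResult,
    b: RankResult,
    method: str = "pearson",
) -> tuple[float, float]:
    """Correlation (r, p) between two rating methods' scores across
    individuals.  ``method`` is 'pearson' (default) or 'spearman'."""
    if a.ids != b.ids:
        raise ValueError("rank results cover different rosters")
    if method == "pearson":
        r, p = stats.pearsonr(a.scores, b.scores)
    elif method == "spearman":
        r, p = stats.spearmanr(a.scores, b.scores)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(r), float(p)
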