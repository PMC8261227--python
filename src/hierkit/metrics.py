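"""Group-level dominance-hierarchy statistics.

Implements the standard battery used to characterize a dominance hierarchy
from a win--lose matrix:

* Landau's h and the de Vries h' linearity index (h' handles tied and
  unobserved dyads by averaging h over random direction assignments; an
  exact closed form of that average is also available),
* triangle transitivity (scaled proportion of transitive fully-directed
  triads),
* directional consistency (how one-sided dyadic outcomes are),
* David's scores, normalized David's scores and hierarchy steepness,
* hierarchy shape (win probability as a function of rank difference),
* subsampling curves of any metric versus sample size.

Statistical significance of each metric is assessed against a null in
which the direction of every event is randomized (winner and loser
swapped with probability 1/2, independently per event).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .events import EventTable, WinLoseMatrix
from .results import TestResult, summarize_null


class UndefinedMetricError(ValueError):
    """Raised when a metric is undefined for the given matrix."""


# ---------------------------------------------------------------------------
# dyad decomposition helpers


def _dyad_counts(W: np.ndarray):
    """Upper-triangle decomposition: (i, j) index arrays, wins for the
    lower-id individual, and dyad totals."""
    iu, ju = np.triu_indices(W.shape[0], k=1)
    upper = W[iu, ju]
    lower = W[ju, iu]
    return iu, ju, upper, upper + lower


def _rebuild(ids, iu, ju, upper, total) -> WinLoseMatrix:
    n = len(ids)
    W = np.zeros((n, n), dtype=int)
    W[iu, ju] = upper
    W[ju, iu] = total - upper
    return WinLoseMatrix(ids, W)


# ---------------------------------------------------------------------------
# linearity


def landau_h(matrix: WinLoseMatrix) -> float:
    """Landau's linearity index h in [0, 1].

    Each dyad is scored 1 for the individual with strictly more wins;
    tied and unobserved dyads contribute 0.5 to both individuals.
    h = [12/(N^3 - N)] * sum_i (V_i - (N-1)/2)^2 with V_i the number of
    individuals i dominates.
    """
    n = matrix.n
    if n < 3:
        raise ValueError("Landau's h requires at least 3 individuals")
    W = matrix.W
    more = (W > W.T).astype(float)
    tie = (W == W.T).astype(float)
    np.fill_diagonal(tie, 0.0)
    V = (more + 0.5 * tie).sum(axis=1)
    return float(12.0 / (n**3 - n) * np.sum((V - (n - 1) / 2.0) ** 2))


@dataclass
class HPrimeResult:
    value: float
    se: float
    n_assign: int
    method: str  # exact | enumerate | mc

    def __float__(self) -> float:
        return self.value


def _hprime_exact(W: np.ndarray) -> float:
    # V_i = d_i + Binomial(u_i, 1/2); E[(V_i - m)^2] = (d_i + u_i/2 - m)^2 + u_i/4
    n = W.shape[0]
    more = (W > W.T).astype(float)
    unknown = (W == W.T).astype(float)
    np.fill_diagonal(unknown, 0.0)
    d = more.sum(axis=1)
    u = unknown.sum(axis=1)
    m = (n - 1) / 2.0
    return float(12.0 / (n**3 - n) * np.sum((d + u / 2.0 - m) ** 2 + u / 4.0))


def devries_h_prime(
    matrix: WinLoseMatrix,
    n_assign: int | None = None,
    seed=None,
) -> HPrimeResult:
    """de Vries h': mean Landau h over random direction assignments of
    every tied or unobserved dyad.

    With ``n_assign=None`` (default) the exact expectation over all
    assignments is returned in closed form (SE = 0).  Otherwise the mean
    is estimated from ``n_assign`` random assignments with its Monte-Carlo
    standard error; when the number of undecided dyads u satisfies
    2^u <= n_assign the 2^u assignments are enumerated exactly instead.
    """
    n = matrix.n
    if n < 3:
        raise ValueError("h' requires at least 3 individuals")
    W = matrix.W
    if n_assign is None:
        return HPrimeResult(_hprime_exact(W), 0.0, 0, "exact")

    more = (W > W.T)
    unknown = np.triu(W == W.T, k=1)
    ui, uj = np.nonzero(unknown)
    u = len(ui)
    d = more.sum(axis=1).astype(float)
    m = (n - 1) / 2.0
    c = 12.0 / (n**3 - n)

    def h_of(assign: np.ndarray) -> float:
        V = d.copy()
        np.add.at(V, np.where(assign, ui, uj), 1.0)
        return c * np.sum((V - m) ** 2)

    if u == 0:
        return HPrimeResult(float(c * np.sum((d - m) ** 2)), 0.0, 1, "enumerate")
    if 2**u <= n_assign:
        vals = [
            h_of(np.array([(k >> b) & 1 for b in range(u)], dtype=bool))
            for k in range(2**u)
        ]
        return HPrimeResult(float(np.mean(vals)), 0.0, 2**u, "enumerate")
    rng = np.random.default_rng(seed)
    vals = np.array([h_of(rng.random(u) < 0.5) for _ in range(n_assign)])
    return HPrimeResult(
        float(vals.mean()), float(vals.std(ddof=1) / np.sqrt(n_assign)),
        n_assign, "mc",
    )


# ---------------------------------------------------------------------------
# transitivity & directional consistency


def triangle_transitivity(matrix: WinLoseMatrix) -> tuple[float, float]:
    """(P_t, t_tri): proportion of fully-directed triads that are
    transitive, and its scaled version t_tri = 4 (P_t - 3/4).

    A dyad is directed when one individual has strictly more wins.  t_tri
    is 1 for a fully transitive set of triads, 0 on average under random
    direction, and -3 if every triad is cyclic.
    """
    W = matrix.W
    D = (W > W.T).astype(float)
    A = D + D.T
    n_triads = np.trace(A @ A @ A) / 6.0
    if n_triads < 0.5:
        raise UndefinedMetricError(
            "no triad has all three dyads directed; triangle transitivity undefined"
        )
    n_cyclic = np.trace(D @ D @ D) / 3.0
    p_t = (n_triads - n_cyclic) / n_triads
    return float(p_t), float(4.0 * (p_t - 0.75))


def directional_consistency(matrix: WinLoseMatrix, pooled: bool = True) -> float:
    """Directional consistency index in [0, 1].

    Pooled (default): sum over dyads of (H - L) divided by the sum of
    (H + L), where H and L are the larger and smaller directional counts
    of each dyad.  ``pooled=False`` returns the unweighted mean of the
    per-dyad ratios instead.
    """
    _, _, upper, total = _dyad_counts(matrix.W)
    active = total > 0
    if not active.any():
        raise UndefinedMetricError("all-zero matrix: directional consistency undefined")
    diff = np.abs(2 * upper - total)
    if pooled:
        return float(diff[active].sum() / total[active].sum())
    return float(np.mean(diff[active] / total[active]))


# ---------------------------------------------------------------------------
# direction-randomization null


def direction_randomization_null(
    data: WinLoseMatrix | EventTable,
    metric_fn,
    n_perm: int = 5000,
    seed=None,
    alternative: str = "greater",
) -> TestResult | dict[str, TestResult]:
    """Permutation test randomizing the direction of every dyadic event.

    Each event's winner and loser are swapped independently with
    probability 1/2; equivalently, the wins of one member of a dyad with
    n events are resampled as Binomial(n, 1/2), which is how replicates
    are generated here.  ``metric_fn`` maps a :class:`WinLoseMatrix` to a
    float or to a dict of named floats (computed jointly per replicate);
    undefined replicates may return NaN and are dropped from the null.

    p-values are one-tailed toward more structure by default.
    """
    if n_perm < 100:
        warnings.warn(
            f"n_perm={n_perm} is very low; p-values will be coarse", stacklevel=2
        )
    matrix = (
        data
        if isinstance(data, WinLoseMatrix)
        else _matrix_from_table(data)
    )
    rng = np.random.default_rng(seed)
    iu, ju, _, total = _dyad_counts(matrix.W)
    observed = metric_fn(matrix)
    as_dict = isinstance(observed, dict)
    obs = observed if as_dict else {"metric": observed}
    null: dict[str, list[float]] = {k: [] for k in obs}
    for _ in range(n_perm):
        upper = rng.binomial(total, 0.5)
        rep = metric_fn(_rebuild(matrix.ids, iu, ju, upper, total))
        rep = rep if as_dict else {"metric": rep}
        for k in obs:
            v = rep[k]
            null[k].append(float(v) if v is not None else np.nan)
    out = {
        k: summarize_null(k, obs[k], np.array(null[k]), alternative, seed=seed)
        for k in obs
    }
    return out if as_dict else out["metric"]


def _matrix_from_table(table: EventTable) -> WinLoseMatrix:
    from .events import build_win_lose_matrix

    return build_win_lose_matrix(table)


def _safe_ttri(m: WinLoseMatrix) -> float:
    try:
        return triangle_transitivity(m)[1]
    except UndefinedMetricError:
        return np.nan


def group_metrics(
    matrix: WinLoseMatrix,
    n_perm: int = 5000,
    seed=None,
) -> dict[str, TestResult]:
    """h, h', t_tri and DC with a shared direction-randomization null.

    Returns a dict of :class:`TestResult` keyed by
    ``landau_h, devries_h_prime, t_tri, dc``; all four metrics are
    evaluated on the same null replicates.
    """

    def all_metrics(m: WinLoseMatrix) -> dict[str, float]:
        return {
            "landau_h": landau_h(m),
            "devries_h_prime": devries_h_prime(m).value,
            "t_tri": _safe_ttri(m),
            "dc": directional_consistency(m),
        }

    return direction_randomization_null(
        matrix, all_metrics, n_perm=n_perm, seed=seed, alternative="greater"
    )


# ---------------------------------------------------------------------------
# David's scores & steepness


@dataclass
class DavidsResult:
    """David's scores and derived quantities.

    DS_i = w_i + w2_i - l_i - l2_i where w is the sum of i's dyadic win
    proportions, w2 weights those by the opponents' w, and l/l2 are the
    symmetric loss terms.  NormDS = (DS + N(N-1)/2)/N lies in [0, N-1].
    Rank 1 is the highest scorer.
    """

    ids: list[str]
    P: np.ndarray
    w: np.ndarray
    w2: np.ndarray
    l: np.ndarray
    l2: np.ndarray
    DS: np.ndarray
    norm_DS: np.ndarray
    ranks: np.ndarray  # 1 = highest DS; average rank on ties

    def rank_order(self) -> list[str]:
        """ids from highest to lowest David's score."""
        return [self.ids[k] for k in np.argsort(-self.DS, kind="stable")]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": self.ids,
                "w": self.w,
                "w2": self.w2,
                "l": self.l,
                "l2": self.l2,
                "DS": self.DS,
                "norm_DS": self.norm_DS,
                "rank": self.ranks,
            }
        )


def davids_scores(matrix: WinLoseMatrix, correction: str = "raw") -> DavidsResult:
    """David's scores from dyadic win proportions.

    ``correction='raw'`` uses P_ij = W_ij / n_ij; ``'dyadic'`` shrinks
    each proportion toward 1/2 by its sample size:
    D_ij = P_ij - (P_ij - 1/2)/(n_ij + 1).  Dyads that never interacted
    contribute nothing.
    """
    W = matrix.W.astype(float)
    n = matrix.n
    totals = matrix.individual_totals()
    isolated = np.where(totals == 0)[0]
    if len(isolated):
        raise ValueError(
            f"individual(s) with no interactions: "
            f"{[matrix.ids[k] for k in isolated]}"
        )
    nij = W + W.T
    with np.errstate(invalid="ignore", divide="ignore"):
        P = np.where(nij > 0, W / np.where(nij > 0, nij, 1), 0.0)
    if correction == "dyadic":
        P = np.where(nij > 0, P - (P - 0.5) / (nij + 1), 0.0)
    elif correction != "raw":
        raise ValueError(f"unknown correction {correction!r}")
    np.fill_diagonal(P, 0.0)
    w = P.sum(axis=1)
    w2 = P @ w
    L = P.T  # L[i, j] = proportion of losses of i to j
    l = L.sum(axis=1)
    l2 = L @ l
    DS = w + w2 - l - l2
    norm_DS = (DS + n * (n - 1) / 2.0) / n
    ranks = stats.rankdata(-DS, method="average")
    return DavidsResult(matrix.ids, P, w, w2, l, l2, DS, norm_DS, ranks)


def steepness_slope(matrix: WinLoseMatrix, correction: str = "raw") -> float:
    """Absolute OLS slope of normalized David's scores against rank 1..N."""
    ds = davids_scores(matrix, correction=correction)
    y = np.sort(ds.norm_DS)[::-1]
    x = np.arange(1, matrix.n + 1, dtype=float)
    slope = np.polyfit(x, y, 1)[0]
    return float(abs(slope))


def steepness(
    matrix: WinLoseMatrix,
    n_perm: int = 5000,
    seed=None,
    correction: str = "raw",
) -> TestResult:
    """Hierarchy steepness with a direction-randomization p-value.

    Steepness near 1 indicates a despotic hierarchy (scores fall quickly
    with rank), near 0 an egalitarian one.
    """
    return direction_randomization_null(
        matrix,
        lambda m: steepness_slope(m, correction=correction),
        n_perm=n_perm,
        seed=seed,
        alternative="greater",
    )


# ---------------------------------------------------------------------------
# hierarchy shape


@dataclass
class ShapeCurve:
    """Win probability of the higher-ranked individual by rank-difference bin."""

    table: pd.DataFrame  # columns: bin_lo, bin_hi, n, prop_higher_won, ci_lo, ci_hi
    n_used: int
    n_tied: int  # events between equally-ranked individuals (excluded)


def _clopper_pearson(k: int, n: int, level: float = 0.95):
    a = (1 - level) / 2
    lo = stats.beta.ppf(a, k, n - k + 1) if k > 0 else 0.0
    hi = stats.beta.ppf(1 - a, k + 1, n - k) if k < n else 1.0
    return float(lo), float(hi)


def hierarchy_shape(
    table: EventTable,
    scores: dict[str, float],
    bin_width: float = 1.0,
) -> ShapeCurve:
    """How well rank differences predict who wins.

    For every usable event the score difference between the two
    participants is computed from ``scores`` (typically David's scores or
    integer ranks, higher = more dominant); events are binned by absolute
    difference and the proportion won by the higher-scored individual is
    reported with an exact (Clopper--Pearson) 95% binomial CI per bin.
    Events between equally-scored individuals have no higher-ranked member
    and are excluded (counted in ``n_tied``).
    """
    ev = table.usable
    unranked = (set(ev["winner"]) | set(ev["loser"])) - set(scores)
    if unranked:
        raise KeyError(f"events involve unranked individuals: {sorted(unranked)}")
    sw = ev["winner"].map(scores).to_numpy(dtype=float)
    sl = ev["loser"].map(scores).to_numpy(dtype=float)
    diff = np.abs(sw - sl)
    higher_won = sw > sl
    tied = sw == sl
    diff, higher_won = diff[~tied], higher_won[~tied]
    bins = np.floor(diff / bin_width).astype(int)
    rows = []
    for b in np.unique(bins):
        sel = bins == b
        n = int(sel.sum())
        k = int(higher_won[sel].sum())
        lo, hi = _clopper_pearson(k, n)
        rows.append(
            {
                "bin_lo": b * bin_width,
                "bin_hi": (b + 1) * bin_width,
                "n": n,
                "prop_higher_won": k / n,
                "ci_lo": lo,
                "ci_hi": hi,
            }
        )
    return ShapeCurve(pd.DataFrame(rows), int(len(diff)), int(tied.sum()))


# ---------------------------------------------------------------------------
# subsampling curve


@dataclass
class SubsampleCurve:
    sizes: np.ndarray
    values: np.ndarray  # shape (n_orders, n_sizes); NaN where undefined
    slope: float  # OLS slope of value on log10(size)
    r2: float


def subsample_metric_curve(
    table: EventTable,
    metric_fn,
    step: int,
    n_orders: int = 1,
    seed=None,
) -> SubsampleCurve:
    """Metric value as a function of the number of events sampled.

    Events are drawn without replacement in random order; the metric is
    recomputed on the cumulative win--lose matrix every ``step`` events.
    Returns the per-size values and the OLS slope (with R^2) of the metric
    against log10 sample size, pooled over orders.
    """
    if step < 1:
        raise ValueError("step must be >= 1")
    ev = table.usable
    n_ev = len(ev)
    if step > n_ev:
        raise ValueError(f"step={step} exceeds the {n_ev} usable events")
    ids = table.ids
    index = {ind: k for k, ind in enumerate(ids)}
    wi = ev["winner"].map(index).to_numpy()
    li = ev["loser"].map(index).to_numpy()
    sizes = np.arange(step, n_ev + 1, step)
    rng = np.random.default_rng(seed)
    values = np.full((n_orders, len(sizes)), np.nan)
    for o in range(n_orders):
        order = rng.permutation(n_ev)
        W = np.zeros((len(ids), len(ids)), dtype=int)
        prev = 0
        for s_idx, size in enumerate(sizes):
            chunk = order[prev:size]
            np.add.at(W, (wi[chunk], li[chunk]), 1)
            prev = size
            try:
                values[o, s_idx] = metric_fn(WinLoseMatrix(ids, W))
            except (UndefinedMetricError, ValueError):
                values[o, s_idx] = np.nan
    x = np.log10(np.tile(sizes, n_orders).astype(float))
    y = values.ravel()
    ok = np.isfinite(y)
    slope, intercept, r, _, _ = stats.linregress(x[ok], y[ok])
    return SubsampleCurve(sizes, values, float(slope), float(r**2))
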