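"""Dyadic-matrix statistics linking dominance rank to cooperation networks.

All statistics ignore the diagonal.  Symmetric matrices (kinship, absolute
rank difference, help symmetry) are vectorized as unordered dyads; directed
matrices (grooming, sharing, signed rank difference) as all ordered
off-diagonal pairs.  Significance comes from node-label permutations
(Mantel, MRQAP with double semi-partialling) or from bootstrap resampling
of individuals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations as iter_permutations

import numpy as np
import pandas as pd

from .events import EventTable
from .results import TestResult, summarize_null

SYMMETRIC_KINDS = {
    "kinship",
    "abs_rank_difference",
    "help_symmetry",
    "co_observation",
    "conflict",
}


@dataclass
class DyadicMatrix:
    """Square matrix of dyadic values with a semantic kind."""

    ids: list[str]
    values: np.ndarray
    kind: str = "generic"
    symmetric: bool | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match ids")
        if self.symmetric is None:
            self.symmetric = self.kind in SYMMETRIC_KINDS or bool(
                np.allclose(self.values, self.values.T, equal_nan=True)
            )

    @property
    def n(self) -> int:
        return len(self.ids)

    def to_csv(self, path) -> None:
        pd.DataFrame(self.values, index=self.ids, columns=self.ids).to_csv(path)

    @classmethod
    def from_csv(cls, path, kind: str = "generic") -> "DyadicMatrix":
        df = pd.read_csv(path, index_col=0)
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        if list(df.index) != list(df.columns):
            raise ValueError("matrix CSV must have identical row and column ids")
        return cls(list(df.index), df.to_numpy(dtype=float), kind=kind)

    def reorder(self, ids: list[str]) -> "DyadicMatrix":
        pos = {i: k for k, i in enumerate(self.ids)}
        missing = [i for i in ids if i not in pos]
        if missing:
            raise KeyError(f"ids missing from {self.kind} matrix: {missing}")
        idx = np.array([pos[i] for i in ids])
        return DyadicMatrix(
            list(ids), self.values[np.ix_(idx, idx)], self.kind, self.symmetric
        )


def log_rate_transform(seconds_total, n_trials):
    """ln(x + 1) transform of a behaviour rate, x = seconds per trial."""
    seconds_total = np.asarray(seconds_total, dtype=float)
    n_trials = np.asarray(n_trials, dtype=float)
    if np.any(n_trials < 1):
        raise ValueError("n_trials must be >= 1")
    if np.any(seconds_total < 0):
        raise ValueError("seconds must be non-negative")
    out = np.log(seconds_total / n_trials + 1.0)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# vectorization helpers


def _cell_indices(n: int, symmetric: bool):
    if symmetric:
        return np.triu_indices(n, k=1)
    mask = ~np.eye(n, dtype=bool)
    return np.nonzero(mask)


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = math.sqrt(float(xc @ xc) * float(yc @ yc))
    if denom == 0:
        raise ValueError("correlation undefined: a matrix is constant off-diagonal")
    return float(xc @ yc) / denom


def _check_same_ids(mats: list[DyadicMatrix]) -> None:
    ids = mats[0].ids
    for m in mats[1:]:
        if m.ids != ids:
            raise ValueError(
                f"matrices cover different ids ({m.kind} vs {mats[0].kind}); "
                "use .reorder() first"
            )


# ---------------------------------------------------------------------------
# Mantel


def mantel(
    A: DyadicMatrix,
    B: DyadicMatrix,
    n_perm: int = 5000,
    seed=None,
    exact: bool | None = None,
) -> TestResult:
    """Mantel test: Pearson r between two dyadic matrices, null from
    simultaneous row/column (node-label) permutations of B; two-tailed.

    With ``exact=True`` (or automatically when N! <= n_perm) all N! node
    permutations are enumerated, giving the exact permutation p-value
    (the identity permutation included, so p > 0 without the add-one term).
    """
    _check_same_ids([A, B])
    n = A.n
    sym = A.symmetric and B.symmetric
    cells = _cell_indices(n, sym)
    a = A.values[cells]
    r_obs = _pearson(a, B.values[cells])
    if exact is None:
        exact = math.factorial(n) <= n_perm
    if exact:
        null = np.array(
            [
                _pearson(a, B.values[np.ix_(p, p)][cells])
                for p in iter_permutations(range(n))
            ]
        )
        res = summarize_null("mantel_r", r_obs, null, "two-sided", seed=seed)
        res.p = float(np.mean(np.abs(null) >= abs(r_obs) - 1e-12))
        res.n_perm = len(null)
        return res
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        p = rng.permutation(n)
        null[i] = _pearson(a, B.values[np.ix_(p, p)][cells])
    return summarize_null("mantel_r", r_obs, null, "two-sided", seed=seed)


# ---------------------------------------------------------------------------
# MRQAP with double semi-partialling


def _design(mats: list[np.ndarray], cells) -> np.ndarray:
    cols = [np.ones(len(cells[0]))] + [m[cells] for m in mats]
    return np.column_stack(cols)


def _ols(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        raise np.linalg.LinAlgError("rank deficient")
    return coef


def mrqap_dsp(
    Y: DyadicMatrix,
    Xs: list[DyadicMatrix],
    n_perm: int = 5000,
    seed=None,
    names: list[str] | None = None,
) -> dict[str, TestResult]:
    """Multiple regression of a dyadic response on dyadic predictors with
    double-semi-partialling node permutations (Dekker-style MRQAP).

    The observed coefficients are the OLS fit (with intercept) on the
    vectorized off-diagonal cells.  For each predictor, the predictor is
    residualized on the remaining predictors, the residual matrix's node
    labels are permuted, the model is refit with the permuted residual in
    place of the predictor, and the permuted-term coefficient forms the
    null; p-values are two-tailed.
    """
    _check_same_ids([Y] + Xs)
    if not Xs:
        raise ValueError("at least one predictor matrix is required")
    n = Y.n
    names = names or [m.kind for m in Xs]
    if len(set(names)) != len(names):
        names = [f"x{k}_{nm}" for k, nm in enumerate(names)]
    sym = Y.symmetric and all(m.symmetric for m in Xs)
    cells = _cell_indices(n, sym)
    y = Y.values[cells]
    if np.all(y == y[0]):
        raise ValueError("response matrix is constant off-diagonal")
    Xfull = _design([m.values for m in Xs], cells)
    # collinearity check with a named culprit
    if np.linalg.matrix_rank(Xfull) < Xfull.shape[1]:
        for a in range(len(Xs)):
            for b in range(a + 1, len(Xs)):
                xa, xb = Xfull[:, a + 1], Xfull[:, b + 1]
                if np.std(xa) == 0 or np.std(xb) == 0 or abs(
                    np.corrcoef(xa, xb)[0, 1]
                ) > 1 - 1e-10:
                    raise ValueError(
                        f"collinear predictors: {names[a]!r} and {names[b]!r}"
                    )
        raise ValueError("design matrix is rank deficient")
    beta = _ols(Xfull, y)
    rng = np.random.default_rng(seed)
    out: dict[str, TestResult] = {}
    for k, name in enumerate(names):
        others = [m.values for j, m in enumerate(Xs) if j != k]
        Xo = _design(others, cells)
        xk = Xs[k].values[cells]
        resid_vec = xk - Xo @ _ols(Xo, xk)
        E = np.zeros((n, n))
        E[cells] = resid_vec
        if sym:
            E = E + E.T
        null = np.empty(n_perm)
        for i in range(n_perm):
            p = rng.permutation(n)
            Ep = E[np.ix_(p, p)]
            Xp = _design(others + [Ep], cells)
            null[i] = _ols(Xp, y)[-1]
        res = summarize_null(name, beta[k + 1], null, "two-sided", seed=seed)
        out[name] = res
    return out


# ---------------------------------------------------------------------------
# rank-difference constructions


def rank_difference_matrices(
    scores: dict[str, float], ids: list[str] | None = None
) -> dict[str, DyadicMatrix]:
    """Signed, absolute, and up-only rank-difference matrices from scores.

    signed[actor, receiver] = score_receiver - score_actor (positive when
    the receiver outranks the actor, i.e. help flowing 'up'); absolute is
    its magnitude; up_only replaces negative differences with zero.
    """
    ids = list(ids) if ids is not None else list(scores)
    s = np.array([scores[i] for i in ids], dtype=float)
    signed = s[None, :] - s[:, None]
    np.fill_diagonal(signed, 0.0)
    return {
        "signed": DyadicMatrix(ids, signed, "rank_difference", symmetric=False),
        "absolute": DyadicMatrix(
            ids, np.abs(signed), "abs_rank_difference", symmetric=True
        ),
        "up_only": DyadicMatrix(
            ids, np.maximum(signed, 0.0), "rank_difference_up", symmetric=False
        ),
    }


def help_symmetry(H: DyadicMatrix) -> DyadicMatrix:
    """Per-dyad helping asymmetry |H_ij - H_ji| / (H_ij + H_ji) in [0, 1].

    0 = perfectly reciprocal, 1 = entirely one-way.  Dyads with no help in
    either direction are NaN (masked from downstream statistics).
    """
    V = H.values
    if np.any(V < 0):
        raise ValueError("help rates must be non-negative")
    total = V + V.T
    with np.errstate(invalid="ignore", divide="ignore"):
        S = np.where(total > 0, np.abs(V - V.T) / np.where(total > 0, total, 1), np.nan)
    np.fill_diagonal(S, np.nan)
    return DyadicMatrix(H.ids, S, "help_symmetry", symmetric=True)


# ---------------------------------------------------------------------------
# directionality of help relative to rank


@dataclass
class DirectionalityResult:
    """Is help directed up the hierarchy?

    ``prop_up`` per individual: fraction of its given help that went to
    higher-ranked partners (chance = 0.5).  ``updown_diff`` per individual:
    mean per-partner rate to higher-ranked minus to lower-ranked partners
    (chance = 0).  CIs are percentile bootstrap over individuals.
    """

    ids: list[str]
    prop_up: dict[str, float]
    prop_up_mean: float
    prop_up_ci: tuple[float, float]
    updown_diff: dict[str, float]
    updown_mean: float
    updown_ci: tuple[float, float]
    excluded: list[str]
    n_boot: int


def _boot_ci(values: np.ndarray, n_boot: int, rng) -> tuple[float, tuple[float, float]]:
    means = np.empty(n_boot)
    n = len(values)
    for b in range(n_boot):
        means[b] = values[rng.integers(0, n, n)].mean()
    lo, hi = np.percentile(means, [2.5, 97.5])
    return float(values.mean()), (float(lo), float(hi))


def help_directionality(
    H: DyadicMatrix,
    scores: dict[str, float],
    n_boot: int = 5000,
    seed=None,
) -> DirectionalityResult:
    """Bootstrap test of whether help flows up the hierarchy."""
    missing = [i for i in H.ids if i not in scores]
    if missing:
        raise KeyError(f"unranked individuals: {missing}")
    rng = np.random.default_rng(seed)
    ids = H.ids
    s = np.array([scores[i] for i in ids])
    V = H.values.copy()
    np.fill_diagonal(V, 0.0)
    higher = s[None, :] > s[:, None]
    lower = s[None, :] < s[:, None]
    given = V.sum(axis=1)
    prop_up, updown, excluded = {}, {}, []
    for k, i in enumerate(ids):
        if given[k] <= 0:
            excluded.append(i)
            continue
        prop_up[i] = float(V[k, higher[k]].sum() / given[k])
        if higher[k].any() and lower[k].any():
            updown[i] = float(V[k, higher[k]].mean() - V[k, lower[k]].mean())
    if not prop_up:
        raise ValueError("no individual gave any help")
    pu = np.array(list(prop_up.values()))
    ud = np.array(list(updown.values()))
    pu_mean, pu_ci = _boot_ci(pu, n_boot, rng)
    ud_mean, ud_ci = _boot_ci(ud, n_boot, rng) if len(ud) else (np.nan, (np.nan, np.nan))
    return DirectionalityResult(
        ids, prop_up, pu_mean, pu_ci, updown, ud_mean, ud_ci, excluded, n_boot
    )


# ---------------------------------------------------------------------------
# feeding time vs rank


def rank_time_permutation_test(
    table: EventTable,
    scores: dict[str, float],
    n_perm: int = 5000,
    seed=None,
) -> TestResult:
    """Does rank predict when individuals are observed at the feeders?

    Each usable event contributes one observation per participating actor
    (winner and loser), pairing the actor's rank score with the event time
    in minutes.  The observed OLS slope of time on rank is compared with
    the slopes obtained when individuals are re-assigned random rank
    labels (each permutation applied consistently to all of an
    individual's observations); two-tailed.
    """
    ev = table.usable
    ids = table.ids
    missing = (set(ev["winner"]) | set(ev["loser"])) - set(scores)
    if missing:
        raise KeyError(f"unranked individuals: {sorted(missing)}")
    idx_of = {i: k for k, i in enumerate(ids)}
    actor_idx = np.concatenate(
        [ev["winner"].map(idx_of).to_numpy(), ev["loser"].map(idx_of).to_numpy()]
    )
    times = np.tile(ev["time_min"].to_numpy(dtype=float), 2)
    s = np.array([scores[i] for i in ids])

    def slope(score_vec: np.ndarray) -> float:
        x = score_vec[actor_idx]
        xc = x - x.mean()
        denom = float(xc @ xc)
        if denom == 0:
            return np.nan
        return float(xc @ (times - times.mean())) / denom

    obs = slope(s)
    rng = np.random.default_rng(seed)
    null = np.array([slope(s[rng.permutation(len(ids))]) for _ in range(n_perm)])
    return summarize_null("rank_time_slope", obs, null, "two-sided", seed=seed)


def conflict_predictors(
    conflict: DyadicMatrix,
    kinship: DyadicMatrix,
    grooming: DyadicMatrix,
    sharing: DyadicMatrix,
    co_observation: DyadicMatrix | None = None,
    n_perm: int = 5000,
    seed=None,
) -> dict[str, TestResult]:
    """MRQAP of conflict rates on kinship, grooming and food sharing,
    optionally controlling for dyadic co-observation counts."""
    if not np.any(conflict.values[~np.eye(conflict.n, dtype=bool)]):
        raise ValueError("conflict matrix is all zero: response undefined")
    Xs = [kinship, grooming, sharing]
    names = ["kinship", "grooming", "sharing"]
    if co_observation is not None:
        Xs.append(co_observation)
        names.append("co_observation")
    return mrqap_dsp(conflict, Xs, n_perm=n_perm, seed=seed, names=names)
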