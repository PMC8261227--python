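"""Shared result containers for permutation and bootstrap procedures."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class TestResult:
    """Observed statistic with its permutation/bootstrap null summary.

    ``p`` uses the add-one correction (1 + #{null at least as extreme})
    / (1 + n_perm), so it is never exactly zero.
    """

    name: str
    observed: float
    null_mean: float
    null_lo95: float
    null_hi95: float
    p: float
    n_perm: int
    alternative: str = "greater"
    seed: int | None = None
    null_samples: np.ndarray | None = field(default=None, repr=False)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "observed": self.observed,
            "null_mean": self.null_mean,
            "null_lo95": self.null_lo95,
            "null_hi95": self.null_hi95,
            "p": self.p,
            "n_perm": self.n_perm,
            "alternative": self.alternative,
            "seed": self.seed,
        }


def permutation_p(observed: float, null: np.ndarray, alternative: str) -> float:
    """Add-one permutation p-value; NaN null replicates are dropped."""
    null = np.asarray(null, dtype=float)
    null = null[np.isfinite(null)]
    m = len(null)
    if alternative == "greater":
        k = int(np.sum(null >= observed))
    elif alternative == "less":
        k = int(np.sum(null <= observed))
    elif alternative == "two-sided":
        k = int(np.sum(np.abs(null) >= abs(observed)))
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return (1 + k) / (1 + m)


def summarize_null(
    name: str,
    observed: float,
    null: np.ndarray,
    alternative: str,
    seed=None,
) -> TestResult:
    null = np.asarray(null, dtype=float)
    finite = null[np.isfinite(null)]
    lo, hi = (
        np.percentile(finite, [2.5, 97.5]) if len(finite) else (np.nan, np.nan)
    )
    return TestResult(
        name=name,
        observed=float(observed),
        null_mean=float(finite.mean()) if len(finite) else float("nan"),
        null_lo95=float(lo),
        null_hi95=float(hi),
        p=permutation_p(observed, null, alternative),
        n_perm=len(null),
        alternative=alternative,
        seed=seed,
        null_samples=null,
    )
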