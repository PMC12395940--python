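"""Global Moran's I with permutation inference.

The statistic uses the binary contiguity matrix by default (weights 0/1,
not row-standardized); inference is by random relabeling of the values
across units with the (k+1)/(M+1) p-value correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .weights import ContiguityMatrix

__all__ = ["MoranResult", "morans_i", "permutation_test"]


@dataclass(frozen=True)
class MoranResult:
    I: float
    expected_I: float
    p_perm: float
    n_perm: int
    seed: int | None
    alternative: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"Moran's I = {self.I:.4f} (E[I] = {self.expected_I:.4f}), "
            f"p = {self.p_perm:.4g} [{self.alternative}, "
            f"{self.n_perm} permutations]"
        )


def _check(x: np.ndarray, W: ContiguityMatrix) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size != W.n:
        raise ValueError(f"x must be a length-{W.n} vector")
    if x.size < 2:
        raise ValueError("Moran's I needs at least 2 units")
    if W.s0 <= 0:
        raise ValueError("weights matrix has no edges")
    if np.ptp(x) == 0:
        raise ValueError("zero variance: x is constant")
    return x


def morans_i(
    x: np.ndarray, W: ContiguityMatrix, row_standardized: bool = False
) -> float:
    """I = (n/S0) * sum_ij w_ij (x_i - xbar)(x_j - xbar) / sum_i (x_i - xbar)^2."""
    x = _check(x, W)
    z = x - x.mean()
    M = W.row_standardized() if row_standardized else W.W
    s0 = M.sum()
    num = float(z @ (M @ z))
    den = float(z @ z)
    return (W.n / s0) * num / den


def permutation_test(
    x: np.ndarray,
    W: ContiguityMatrix,
    n_perm: int = 999,
    seed: int | None = None,
    alternative: str = "greater",
    row_standardized: bool = False,
) -> MoranResult:
    """Permutation test for Moran's I.

    One-sided positive alternative by default (clustering of like values);
    ``alternative='two-sided'`` doubles the smaller tail (capped at 1).
    """
    if n_perm < 99:
        raise ValueError("use at least 99 permutations")
    if alternative not in ("greater", "less", "two-sided"):
        raise ValueError(f"unknown alternative {alternative!r}")
    x = _check(x, W)
    obs = morans_i(x, W, row_standardized=row_standardized)

    rng = np.random.default_rng(seed)
    z = x - x.mean()
    den = float(z @ z)
    M = W.row_standardized() if row_standardized else W.W
    s0 = M.sum()
    scale = W.n / (s0 * den)
    sims = np.empty(n_perm)
    for b in range(n_perm):
        zp = rng.permutation(z)
        sims[b] = scale * float(zp @ (M @ zp))

    p_hi = (1 + np.sum(sims >= obs)) / (1 + n_perm)
    p_lo = (1 + np.sum(sims <= obs)) / (1 + n_perm)
    if alternative == "greater":
        p = p_hi
    elif alternative == "less":
        p = p_lo
    else:
        p = min(1.0, 2 * min(p_hi, p_lo))
    return MoranResult(
        I=obs,
        expected_I=-1.0 / (W.n - 1),
        p_perm=float(p),
        n_perm=n_perm,
        seed=seed,
        alternative=alternative,
    )
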