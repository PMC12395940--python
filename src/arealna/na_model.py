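"""Neighborhood-adjustment (NA) causal estimator via spatial smoothing.

Augments the spatial Poisson model with a spatially smoothed copy of the
exposure.  When unobserved confounding varies at a broader spatial scale
than the exposure, the smoothed exposure proxies the confounder; adjusting
for it (coefficient delta) lets the exposure coefficient beta_x recover
the causal effect from the fine-scale exposure variation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .spatial_model import ModelConfig, PosteriorDraws, build_design, run_mcmc
from .weights import ContiguityMatrix

__all__ = [
    "NAConfig",
    "NAResult",
    "smooth_exposure",
    "fit_na",
    "positivity_check",
    "PositivityReport",
]


@dataclass(frozen=True)
class NAConfig(ModelConfig):
    """Spatial-model config plus the exposure-smoother settings."""

    smoother: str = "row_standardized_neighbor_mean"
    k_smooth: int = 1
    include_self: bool = False

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.smoother not in ("row_standardized_neighbor_mean", "iterated_k"):
            raise ValueError(f"unknown smoother {self.smoother!r}")
        if self.k_smooth < 1:
            raise ValueError("k_smooth must be >= 1")


@dataclass
class PositivityReport:
    """Within-stratum exposure overlap given the smoothed exposure."""

    table: pd.DataFrame  # per stratum: n, x_min, x_max, x_range, degenerate
    n_bins: int
    any_flagged: bool

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        status = "FLAGGED" if self.any_flagged else "ok"
        return f"positivity check ({self.n_bins} strata): {status}\n" + str(
            self.table
        )


@dataclass
class NAResult:
    """Posterior draws from the NA model with named exposure components."""

    draws: PosteriorDraws
    positivity: PositivityReport
    smoothed_exposure: np.ndarray

    @property
    def beta_na(self) -> np.ndarray:
        """Draws of the adjusted (causal) exposure effect."""
        return self.draws.coef("x")

    @property
    def delta(self) -> np.ndarray:
        """Draws of the smoothed-exposure adjustment coefficient."""
        return self.draws.coef("x_smooth")


def smooth_exposure(
    x: np.ndarray, W: ContiguityMatrix, config: NAConfig | None = None
) -> np.ndarray:
    """Row-standardized neighbor-mean smoothing of the exposure.

    Applies s = W_rs @ x (or (I + W_rs)/2 @ x when ``include_self``)
    ``k_smooth`` times.  Constants are preserved.  Islands make the pure
    neighbor mean undefined, so they must be excluded (or use
    ``include_self``).
    """
    config = config or NAConfig()
    x = np.asarray(x, dtype=float)
    if x.size != W.n:
        raise ValueError(f"x must have length {W.n}")
    if W.islands.size and not config.include_self:
        isl = [W.unit_ids[i] for i in W.islands]
        raise ValueError(
            f"islands present ({isl}); exclude them or set include_self=True"
        )
    S = W.row_standardized()
    if config.include_self:
        S = (sp.eye(W.n, format="csr") + S) * 0.5
        if W.islands.size:  # islands keep their own value
            D = sp.lil_matrix((W.n, W.n))
            for i in W.islands:
                D[i, i] = 0.5
            S = (S + D.tocsr()).tocsr()
    s = x
    for _ in range(config.k_smooth):
        s = S @ s
    return s


def positivity_check(
    x: np.ndarray, s: np.ndarray, n_bins: int = 5
) -> PositivityReport:
    """Overlap diagnostic: does the exposure vary within strata of s?

    Bins the smoothed exposure into ``n_bins`` quantile strata.  The
    identifying variation within a stratum is the exposure variation not
    explained by s, so each stratum reports the range of the residual of
    x regressed on s alongside the raw x range; a stratum is degenerate
    when that residual range is under 10% of the overall exposure range
    (the effect is not identified there).
    """
    x = np.asarray(x, dtype=float)
    s = np.asarray(s, dtype=float)
    if n_bins < 3:
        raise ValueError("need at least 3 strata")
    if n_bins > x.size:
        raise ValueError(f"n_bins={n_bins} exceeds the number of units {x.size}")
    overall = float(np.ptp(x))
    if s.std() > 0:
        slope = float(np.cov(x, s)[0, 1] / s.var())
        resid = x - x.mean() - slope * (s - s.mean())
    else:
        resid = x - x.mean()
    qs = np.quantile(s, np.linspace(0, 1, n_bins + 1))
    # constant s collapses all quantiles: keep one stratum per requested bin
    bins = np.clip(np.searchsorted(qs, s, side="right") - 1, 0, n_bins - 1)
    rows = []
    for b in range(n_bins):
        mask = bins == b
        if not mask.any():
            rows.append((b, 0, np.nan, np.nan, 0.0, 0.0, True))
            continue
        xb = x[mask]
        rng_b = float(np.ptp(xb))
        resid_b = float(np.ptp(resid[mask]))
        degenerate = overall == 0 or resid_b < 0.1 * overall
        rows.append(
            (b, int(mask.sum()), xb.min(), xb.max(), rng_b, resid_b, degenerate)
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "stratum", "n", "x_min", "x_max", "x_range", "resid_range",
            "degenerate",
        ],
    )
    return PositivityReport(
        table=table, n_bins=n_bins, any_flagged=bool(table["degenerate"].any())
    )


def fit_na(
    areas: pd.DataFrame,
    smr: pd.DataFrame,
    W: ContiguityMatrix,
    config: NAConfig | None = None,
) -> NAResult:
    """Fit the NA model: spatial model plus smoothed-exposure adjustment.

    y_i ~ Poisson(E_i exp(beta0 + beta_x x_i + delta s_i + gamma'z_i + phi_i))
    with s = smooth_exposure(x).  ``beta_na`` on the result is the draws of
    beta_x, reported as the causal exposure effect.
    """
    config = config or NAConfig()
    keep = np.flatnonzero(smr["E"].to_numpy() > 0)
    if keep.size < len(smr):
        dropped = smr.loc[smr["E"] <= 0, "unit_id"].tolist()
        warnings.warn(
            f"excluding {len(dropped)} unit(s) with zero expected count: "
            f"{dropped}",
            stacklevel=2,
        )
        areas = areas.iloc[keep].reset_index(drop=True)
        smr = smr.iloc[keep].reset_index(drop=True)
        W = W.subset(keep)

    x = areas["x"].to_numpy(dtype=float)
    s = smooth_exposure(x, W, config)
    if x.std() > 0 and s.std() > 0:
        r = float(np.corrcoef(x, s)[0, 1])
        if abs(r) > 0.99:
            raise ValueError(
                f"smoothed exposure nearly collinear with exposure (r={r:.4f}); "
                "increase k_smooth or use a coarser smoother"
            )
    X, names = build_design(areas, config, extra={"x_smooth": s})
    draws = run_mcmc(
        y=smr["O"].to_numpy(),
        E=smr["E"].to_numpy(),
        X=X,
        coef_names=names,
        W=W if config.spatial_effects else None,
        config=config,
        unit_ids=tuple(areas["unit_id"].astype(str)),
    )
    report = positivity_check(x, s, n_bins=min(5, max(3, len(areas) // 20 or 3)))
    return NAResult(draws=draws, positivity=report, smoothed_exposure=s)
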