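"""Posterior effect summaries and relative-risk density curves.

Coefficients are reported on the log scale (a coefficient of -0.029 reads
as a 2.9% decrease in the rate per one-unit exposure increase) and on the
relative-risk scale exp(beta).  "Significant" means the equal-tailed 95%
credible interval excludes zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .spatial_model import PosteriorDraws

__all__ = ["summarize", "rr_density", "RRCurve", "effects_table", "format_cell"]

_QLO, _QHI = 2.5, 97.5


def _check_draws(draws: PosteriorDraws) -> None:
    if draws.n_draws == 0:
        raise ValueError("no posterior draws to summarize")
    if draws.n_draws < 100:
        import warnings

        warnings.warn(
            f"only {draws.n_draws} draws; summaries will be noisy", stacklevel=3
        )


def summarize(draws: PosteriorDraws) -> pd.DataFrame:
    """Per-coefficient posterior mean, 95% CrI, and relative-risk scale.

    Returns a frame indexed by coefficient name with columns mean, lo,
    hi, significant, rr_mean, rr_lo, rr_hi.  The RR bounds are the
    elementwise exp of the coefficient bounds (monotone transform of the
    same draws); rr_mean is the posterior mean of exp(beta).
    """
    _check_draws(draws)
    b = draws.beta
    lo, hi = np.percentile(b, [_QLO, _QHI], axis=0)
    mean = b.mean(axis=0)
    rr = np.exp(b)
    return pd.DataFrame(
        {
            "mean": mean,
            "lo": lo,
            "hi": hi,
            "significant": (lo > 0) | (hi < 0),
            "rr_mean": rr.mean(axis=0),
            "rr_lo": np.exp(lo),
            "rr_hi": np.exp(hi),
        },
        index=list(draws.coef_names),
    )


@dataclass(frozen=True)
class RRCurve:
    """Kernel density of exp(beta) draws with posterior annotations."""

    grid: np.ndarray
    density: np.ndarray
    mean: float
    lo: float
    hi: float


def rr_density(
    draws: PosteriorDraws, covariate: str = "x", gridsize: int = 512
) -> RRCurve:
    """Posterior density of the exponentiated coefficient (relative risk).

    Gaussian KDE (Scott bandwidth) on the exp(beta) draws; degenerate
    (point-mass) posteriors fall back to a very narrow Gaussian spike so
    the curve still peaks at exp(c).
    """
    _check_draws(draws)
    rr = np.exp(draws.coef(covariate))
    mean = float(rr.mean())
    lo, hi = (float(v) for v in np.percentile(rr, [_QLO, _QHI]))
    sd = rr.std()
    if sd == 0:
        width = max(abs(mean) * 1e-6, 1e-12)
        grid = np.linspace(mean - 8 * width, mean + 8 * width, gridsize)
        dens = np.exp(-0.5 * ((grid - mean) / width) ** 2) / (
            width * np.sqrt(2 * np.pi)
        )
        return RRCurve(grid=grid, density=dens, mean=mean, lo=lo, hi=hi)
    from scipy.stats import gaussian_kde

    kde = gaussian_kde(rr)
    pad = 4 * kde.factor * sd
    grid = np.linspace(rr.min() - pad, rr.max() + pad, gridsize)
    return RRCurve(grid=grid, density=kde(grid), mean=mean, lo=lo, hi=hi)


def format_cell(mean: float, lo: float, hi: float, digits: int = 3) -> str:
    """'-0.029 (-0.055 to -0.003)' style cell."""
    f = f"{{:.{digits}f}}"
    return f"{f.format(mean)} ({f.format(lo)} to {f.format(hi)})"


def effects_table(
    summaries: dict[tuple[str, str], pd.DataFrame],
    covariates: list[str] | None = None,
    digits: int = 3,
) -> pd.DataFrame:
    """Two-panel effects table: outcomes x models, one row per covariate.

    ``summaries`` maps (outcome, model) -> the frame from :func:`summarize`;
    cells are 'mean (lo to hi)' strings.  Intercept and the smoothed
    exposure adjustment are omitted (report rows are the substantive
    effects only).
    """
    drop = {"intercept", "x_smooth"}
    rows = []
    outcomes = sorted({k[0] for k in summaries})
    models = sorted({k[1] for k in summaries})
    if covariates is None:
        any_summary = next(iter(summaries.values()))
        covariates = [c for c in any_summary.index if c not in drop]
    for outcome in outcomes:
        for cov in covariates:
            row: dict[str, str] = {"outcome": outcome, "covariate": cov}
            for model in models:
                key = (outcome, model)
                if key in summaries and cov in summaries[key].index:
                    r = summaries[key].loc[cov]
                    row[model] = format_cell(r["mean"], r["lo"], r["hi"], digits)
                else:
                    row[model] = ""
            rows.append(row)
    return pd.DataFrame(rows)


def plot_rr_density(
    curves: dict[str, RRCurve], path: str | Path, title: str = ""
) -> None:
    """Overlaid RR density curves (one per model) to SVG/PNG."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for label, curve in curves.items():
        ax.plot(curve.grid, curve.density, label=f"{label} (mean {curve.mean:.3f})")
        ax.axvline(curve.mean, ls="--", lw=0.8)
    ax.axvline(1.0, color="k", lw=0.8)
    ax.set_xlabel("relative risk exp(beta)")
    ax.set_ylabel("posterior density")
    if title:
        ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
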