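"""Bayesian spatial Poisson regression with an ICAR random effect.

Model:  y_i ~ Poisson(E_i * exp(beta0 + beta_x x_i + gamma'z_i + phi_i)),
phi | tau ~ ICAR(W, tau) with a sum-to-zero constraint per connected
component, Gaussian(0, prior_sd) priors on all regression coefficients and
a Gamma prior on the ICAR precision tau.

Sampling is Metropolis-within-Gibbs: adaptive random-walk updates for the
coefficients, chromatic (graph-colored) blocked random-walk updates for
phi, and a conjugate Gamma draw for tau.  Chains are reproducible under
the config seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .areas import COVARIATES
from .weights import ContiguityMatrix

__all__ = [
    "ModelConfig",
    "PosteriorDraws",
    "icar_logdensity",
    "poisson_loglik",
    "fit_spatial",
]


@dataclass(frozen=True)
class ModelConfig:
    """Sampler and prior settings shared by the spatial and NA models."""

    covariates: tuple[str, ...] = COVARIATES
    prior_sd: float = 10.0
    tau_prior: tuple[float, float] = (1.0, 0.01)  # Gamma(shape, rate)
    n_iter: int = 20000
    n_burn: int = 5000
    n_chains: int = 2
    thin: int = 5
    seed: int = 0
    island_policy: str = "exclude"  # or "iid_effect"
    spatial_effects: bool = True  # False: phi fixed at 0 (tau -> inf limit)

    def __post_init__(self) -> None:
        if not self.n_iter > self.n_burn >= 0:
            raise ValueError("need n_iter > n_burn >= 0")
        if self.prior_sd <= 0:
            raise ValueError("prior_sd must be positive")
        if self.thin < 1 or self.n_chains < 1:
            raise ValueError("thin and n_chains must be >= 1")
        if self.island_policy not in ("exclude", "iid_effect"):
            raise ValueError(f"unknown island_policy {self.island_policy!r}")


@dataclass
class PosteriorDraws:
    """Pooled post-burn-in MCMC draws plus convergence diagnostics.

    ``beta`` has one column per entry of ``coef_names`` (intercept first,
    exposure second).  ``phi`` columns follow ``unit_ids``; ``tau`` is
    empty when spatial effects were disabled.
    """

    coef_names: tuple[str, ...]
    beta: np.ndarray  # (n_draws, p)
    phi: np.ndarray  # (n_draws, n)
    tau: np.ndarray  # (n_draws,) or empty
    unit_ids: tuple[str, ...]
    n_chains: int
    diagnostics: pd.DataFrame = field(repr=False)  # rhat, ess per coefficient
    acceptance: dict = field(default_factory=dict, repr=False)

    @property
    def n_draws(self) -> int:
        return self.beta.shape[0]

    def coef(self, name: str) -> np.ndarray:
        return self.beta[:, self.coef_names.index(name)]

    def to_frame(self) -> pd.DataFrame:
        """Wide draw table (chain, draw, coefficients, tau, phi columns)."""
        per_chain = self.n_draws // self.n_chains
        cols: dict[str, np.ndarray] = {
            "chain": np.repeat(np.arange(self.n_chains), per_chain),
            "draw": np.tile(np.arange(per_chain), self.n_chains),
        }
        for j, name in enumerate(self.coef_names):
            cols[f"b_{name}"] = self.beta[:, j]
        cols["tau"] = self.tau if self.tau.size else np.full(self.n_draws, np.nan)
        for i, uid in enumerate(self.unit_ids):
            cols[f"phi_{uid}"] = self.phi[:, i]
        return pd.DataFrame(cols)

    def save(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def load(cls, path: str | Path) -> "PosteriorDraws":
        df = pd.read_csv(path)
        coef_names = tuple(c[2:] for c in df.columns if c.startswith("b_"))
        unit_ids = tuple(c[4:] for c in df.columns if c.startswith("phi_"))
        beta = df[[f"b_{c}" for c in coef_names]].to_numpy()
        phi = df[[f"phi_{u}" for u in unit_ids]].to_numpy()
        tau = df["tau"].to_numpy()
        if np.isnan(tau).all():
            tau = np.empty(0)
        n_chains = int(df["chain"].max()) + 1
        return cls(
            coef_names=coef_names,
            beta=beta,
            phi=phi,
            tau=tau,
            unit_ids=unit_ids,
            n_chains=n_chains,
            diagnostics=pd.DataFrame(index=list(coef_names)),
        )


def poisson_loglik(y: np.ndarray, E: np.ndarray, eta_lin: np.ndarray) -> float:
    """Poisson log-likelihood (up to the y! constant) with offset E.

    ``eta_lin`` is the linear predictor excluding the offset, so the mean
    is E * exp(eta_lin).
    """
    mu = E * np.exp(eta_lin)
    return float(np.sum(y * (np.log(E) + eta_lin) - mu))


def icar_logdensity(
    phi: np.ndarray, tau: float, W: ContiguityMatrix, check: bool = True
) -> float:
    """Unnormalized ICAR log density.

    log p = ((n - c)/2) log tau - (tau/2) sum_{i~j} (phi_i - phi_j)^2,
    with c the number of connected components and the sum over undirected
    edges.  phi must satisfy the per-component sum-to-zero constraint.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    phi = np.asarray(phi, dtype=float)
    if phi.size != W.n:
        raise ValueError("phi length must match W")
    labels = W.components()
    c = labels.max() + 1
    if check:
        for lab in range(c):
            s = phi[labels == lab].sum()
            if abs(s) > 1e-6 * max(1.0, np.abs(phi).max()):
                raise ValueError(
                    f"phi violates sum-to-zero on component {lab} (sum={s:.3g})"
                )
    edges = W.edge_array()
    q = float(np.sum((phi[edges[:, 0]] - phi[edges[:, 1]]) ** 2)) if len(edges) else 0.0
    return 0.5 * (W.n - c) * np.log(tau) - 0.5 * tau * q


# ---------------------------------------------------------------------------
# sampler internals
# ---------------------------------------------------------------------------


def _greedy_coloring(W: ContiguityMatrix, nodes: np.ndarray) -> list[np.ndarray]:
    """Partition ``nodes`` into independent sets of the induced subgraph."""
    import networkx as nx

    G = nx.Graph()
    G.add_nodes_from(nodes.tolist())
    sub = set(nodes.tolist())
    for i, j in W.edge_array():
        if i in sub and j in sub:
            G.add_edge(int(i), int(j))
    colors = nx.coloring.greedy_color(G, strategy="largest_first")
    n_colors = max(colors.values()) + 1 if colors else 0
    return [
        np.array(sorted(v for v, c in colors.items() if c == col), dtype=int)
        for col in range(n_colors)
    ]


def _check_full_rank(X: np.ndarray, names: tuple[str, ...]) -> None:
    _, R = np.linalg.qr(X)
    diag = np.abs(np.diag(R))
    bad = diag < 1e-8 * max(1.0, diag.max())
    if bad.any():
        cols = [names[i] for i in np.flatnonzero(bad)]
        raise ValueError(f"design matrix is rank deficient; collinear columns: {cols}")


def _run_chain(
    y: np.ndarray,
    E: np.ndarray,
    X: np.ndarray,
    prior_sd_vec: np.ndarray,
    W: ContiguityMatrix | None,
    config: ModelConfig,
    chain: int,
) -> dict:
    rng = np.random.default_rng([config.seed, 2718, chain])
    n, p = X.shape
    prior_var = prior_sd_vec**2
    a0, b0 = config.tau_prior

    spatial = config.spatial_effects and W is not None
    if spatial:
        degrees = W.degrees
        labels = W.components()
        comp_sizes = np.bincount(labels)
        icar_nodes = np.flatnonzero(comp_sizes[labels] >= 2)
        island_nodes = np.flatnonzero(comp_sizes[labels] == 1)
        icar_comps = [
            np.flatnonzero(labels == lab)
            for lab in range(labels.max() + 1)
            if comp_sizes[lab] >= 2
        ]
        c_icar = len(icar_comps)
        blocks = _greedy_coloring(W, icar_nodes)
        block_rows = [W.W[b] for b in blocks]
        edges = W.edge_array()
        iid_islands = config.island_policy == "iid_effect" and island_nodes.size > 0
        # absorbing the recentered mean into the intercept keeps the
        # likelihood invariant only when every modelled unit shifts
        absorb = c_icar == 1 and island_nodes.size == 0
    else:
        iid_islands = False
        island_nodes = np.empty(0, dtype=int)

    beta = np.zeros(p)
    beta[0] = np.log(max(y.sum(), 0.5) / E.sum())
    phi = np.zeros(n)
    tau = 1.0

    eta = X @ beta + phi  # linear predictor excluding offset
    mu = E * np.exp(eta)

    step_beta = np.full(p, 0.1)
    acc_beta = np.zeros(p)
    try_beta = np.zeros(p)
    if spatial:
        step_phi = np.full(n, 0.5)
        acc_phi = np.zeros(n)
        try_phi = np.zeros(n)

    n_keep = (config.n_iter - config.n_burn) // config.thin
    out_beta = np.empty((n_keep, p))
    out_phi = np.empty((n_keep, n))
    out_tau = np.empty(n_keep) if spatial else np.empty(0)
    kept = 0

    for it in range(config.n_iter):
        # --- regression coefficients: single-site random walk
        for j in range(p):
            prop = step_beta[j] * rng.standard_normal()
            d_eta = X[:, j] * prop
            new_eta = eta + d_eta
            new_mu = E * np.exp(new_eta)
            d_ll = float(y @ d_eta - (new_mu.sum() - mu.sum()))
            bj = beta[j]
            d_prior = (bj**2 - (bj + prop) ** 2) / (2 * prior_var[j])
            try_beta[j] += 1
            if np.log(rng.uniform()) < d_ll + d_prior:
                beta[j] = bj + prop
                eta = new_eta
                mu = new_mu
                acc_beta[j] += 1

        if spatial:
            # --- phi: chromatic blocks (no edges inside a block, so
            # per-site accept/reject decisions are independent)
            for b_idx, (B, WB) in enumerate(zip(blocks, block_rows)):
                nbr = WB @ phi
                d_lin = step_phi[B] * rng.standard_normal(B.size)
                prop = phi[B] + d_lin
                d_ll = y[B] * d_lin - mu[B] * (np.exp(d_lin) - 1.0)
                d_prior = -0.5 * tau * (
                    degrees[B] * (prop**2 - phi[B] ** 2) - 2.0 * d_lin * nbr
                )
                acc = np.log(rng.uniform(size=B.size)) < d_ll + d_prior
                try_phi[B] += 1
                if acc.any():
                    upd = B[acc]
                    phi[upd] += d_lin[acc]
                    eta[upd] += d_lin[acc]
                    mu[upd] = E[upd] * np.exp(eta[upd])
                    acc_phi[upd] += 1

            if iid_islands:
                Bi = island_nodes
                d_lin = step_phi[Bi] * rng.standard_normal(Bi.size)
                d_ll = y[Bi] * d_lin - mu[Bi] * (np.exp(d_lin) - 1.0)
                d_prior = -0.5 * tau * ((phi[Bi] + d_lin) ** 2 - phi[Bi] ** 2)
                acc = np.log(rng.uniform(size=Bi.size)) < d_ll + d_prior
                try_phi[Bi] += 1
                if acc.any():
                    upd = Bi[acc]
                    phi[upd] += d_lin[acc]
                    eta[upd] += d_lin[acc]
                    mu[upd] = E[upd] * np.exp(eta[upd])
                    acc_phi[upd] += 1

            # --- sum-to-zero per ICAR component
            if absorb:
                m = phi[icar_comps[0]].mean()
                phi[icar_comps[0]] -= m
                beta[0] += m  # eta unchanged
            else:
                for comp in icar_comps:
                    phi[comp] -= phi[comp].mean()
                eta = X @ beta + phi
                mu = E * np.exp(eta)

            # --- conjugate precision update
            q = float(np.sum((phi[edges[:, 0]] - phi[edges[:, 1]]) ** 2))
            shape = a0 + 0.5 * (icar_nodes.size - c_icar)
            rate = b0 + 0.5 * q
            if iid_islands:
                shape += 0.5 * island_nodes.size
                rate += 0.5 * float(np.sum(phi[island_nodes] ** 2))
            tau = rng.gamma(shape, 1.0 / rate)

        if not np.isfinite(mu).all() or not np.isfinite(eta).all():
            raise FloatingPointError(
                f"sampler diverged (non-finite state) at iteration {it}"
            )

        # --- step-size adaptation during burn-in, 20-40% target
        if it < config.n_burn and (it + 1) % 50 == 0:
            delta = min(0.25, (1.0 + it / 50.0) ** -0.5)
            rates = np.divide(acc_beta, np.maximum(try_beta, 1))
            step_beta *= np.exp(delta * (rates - 0.3))
            acc_beta[:] = 0
            try_beta[:] = 0
            if spatial:
                rates = np.divide(acc_phi, np.maximum(try_phi, 1))
                step_phi *= np.exp(delta * (rates - 0.3))
                acc_phi[:] = 0
                try_phi[:] = 0

        if it >= config.n_burn and (it - config.n_burn) % config.thin == 0:
            if kept < n_keep:
                out_beta[kept] = beta
                out_phi[kept] = phi
                if spatial:
                    out_tau[kept] = tau
                kept += 1

    return {
        "beta": out_beta[:kept],
        "phi": out_phi[:kept],
        "tau": out_tau[:kept] if spatial else out_tau,
        "acc_beta": np.divide(acc_beta, np.maximum(try_beta, 1)),
        "acc_phi": (
            np.divide(acc_phi, np.maximum(try_phi, 1)) if spatial else None
        ),
    }


def _diagnostics(
    beta_chains: np.ndarray, coef_names: tuple[str, ...]
) -> pd.DataFrame:
    """Split-R-hat and bulk ESS per coefficient via arviz.

    A single chain is split in half so R-hat is still defined.
    """
    import logging

    import arviz as az

    if beta_chains.shape[0] == 1 and beta_chains.shape[1] >= 8:
        half = beta_chains.shape[1] // 2
        beta_chains = np.stack(
            [beta_chains[0, :half], beta_chains[0, half : 2 * half]]
        )
    logging.getLogger("arviz").setLevel(logging.ERROR)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        idata = az.from_dict(posterior={"beta": beta_chains})
        rhat = az.rhat(idata)["beta"].values
        ess = az.ess(idata)["beta"].values
    return pd.DataFrame({"rhat": rhat, "ess": ess}, index=list(coef_names))


def run_mcmc(
    y: np.ndarray,
    E: np.ndarray,
    X: np.ndarray,
    coef_names: tuple[str, ...],
    W: ContiguityMatrix | None,
    config: ModelConfig,
    unit_ids: tuple[str, ...],
) -> PosteriorDraws:
    """Shared sampler entry point for the spatial and NA models."""
    y = np.asarray(y, dtype=float)
    E = np.asarray(E, dtype=float)
    X = np.asarray(X, dtype=float)
    if (E <= 0).any():
        raise ValueError("all expected counts must be positive")
    _check_full_rank(X, coef_names)

    # sample on unit-sd columns for well-mixed random walks; the prior
    # stays on the raw-scale coefficients (sd prior_sd per coefficient),
    # and draws are mapped back, so the fitted model is unchanged
    scale = X.std(axis=0)
    scale[scale == 0] = 1.0  # intercept (and any constant column)
    Xs = X / scale
    prior_sd_vec = config.prior_sd * scale

    chains = [
        _run_chain(y, E, Xs, prior_sd_vec, W, config, chain)
        for chain in range(config.n_chains)
    ]
    for c in chains:
        c["beta"] /= scale
    beta_chains = np.stack([c["beta"] for c in chains])  # (chains, draws, p)
    diag = _diagnostics(beta_chains, coef_names)
    bad = diag.index[diag["rhat"] > 1.05].tolist()
    if bad:
        warnings.warn(
            f"R-hat > 1.05 for {bad}; consider longer chains", stacklevel=2
        )

    draws = PosteriorDraws(
        coef_names=coef_names,
        beta=beta_chains.reshape(-1, X.shape[1]),
        phi=np.concatenate([c["phi"] for c in chains]),
        tau=np.concatenate([c["tau"] for c in chains]),
        unit_ids=unit_ids,
        n_chains=config.n_chains,
        diagnostics=diag,
        acceptance={
            "beta": np.mean([c["acc_beta"] for c in chains], axis=0),
            "phi": (
                np.mean([c["acc_phi"] for c in chains], axis=0)
                if chains[0]["acc_phi"] is not None
                else None
            ),
        },
    )
    return draws


def build_design(
    areas: pd.DataFrame, config: ModelConfig, extra: dict[str, np.ndarray] | None = None
) -> tuple[np.ndarray, tuple[str, ...]]:
    """Intercept + exposure + covariates design, covariates mean-centered.

    Centering leaves all non-intercept coefficients on their original
    scale (so effect sizes stay interpretable per unit of the raw
    variable) while decorrelating them from the intercept.
    """
    cols: list[np.ndarray] = [np.ones(len(areas))]
    names: list[str] = ["intercept", "x"]
    x = areas["x"].to_numpy(dtype=float)
    cols.append(x - x.mean())
    if extra:
        for name, v in extra.items():
            names.append(name)
            cols.append(v - v.mean())
    for cov in config.covariates:
        names.append(cov)
        v = areas[cov].to_numpy(dtype=float)
        cols.append(v - v.mean())
    return np.column_stack(cols), tuple(names)


def fit_spatial(
    areas: pd.DataFrame,
    smr: pd.DataFrame,
    W: ContiguityMatrix,
    config: ModelConfig | None = None,
) -> PosteriorDraws:
    """Fit the classical Bayesian spatial model.

    Units with zero expected count are excluded with a warning; the
    contiguity matrix is restricted to the modelled units.
    """
    config = config or ModelConfig()
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
    X, names = build_design(areas, config)
    return run_mcmc(
        y=smr["O"].to_numpy(),
        E=smr["E"].to_numpy(),
        X=X,
        coef_names=names,
        W=W,
        config=config,
        unit_ids=tuple(areas["unit_id"].astype(str)),
    )
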