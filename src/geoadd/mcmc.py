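"""Pólya-Gamma-augmented Gibbs sampler for the geoadditive logistic model.

Augmenting each observation with omega_i ~ PG(1, eta_i) makes every
coefficient block conditionally Gaussian (Polson-Scott-Windle), so the chain
is a systematic-scan Gibbs sampler with exact conditionals and no rejection
steps: augmentation draw, intercept, each coefficient block, each variance
parameter. Penalized and spatial blocks are re-centred to sum to zero after
every draw, with the removed mean folded into the intercept (the ICAR prior
is improper, so the level of a spatial block is not identified).

The default schedule is 10,000 burn-in iterations followed by
40,000 iterations with every 20th state stored, yielding 2,000 stored
draws. The deviance -2 log L(y, eta) is recorded at every stored
state and the posterior mean of eta is accumulated for DIC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve, solve_triangular

from .design import PenaltyMatrix
from .model import ModelSpec, deviance as _deviance
from .pg import random_polya_gamma

__all__ = [
    "MCMCConfig",
    "PosteriorDraws",
    "draw_augmentation",
    "update_block",
    "update_variance",
    "run_chain",
    "diagnostics",
]


@dataclass(frozen=True)
class MCMCConfig:
    """Chain schedule and variance hyperprior.

    Defaults give the full 10,000/40,000/20 schedule; ``iterations`` counts
    post-burn-in sweeps and must be divisible by ``thin``.
    """

    burn_in: int = 10_000
    iterations: int = 40_000
    thin: int = 20
    seed: int = 0
    a: float = 0.001
    b: float = 0.001

    def __post_init__(self):
        if self.burn_in < 0 or self.iterations <= 0 or self.thin <= 0:
            raise ValueError("chain lengths must be positive")
        if self.iterations % self.thin != 0:
            raise ValueError(
                f"iterations ({self.iterations}) must be divisible by thin ({self.thin})"
            )
        if self.a <= 0 or self.b <= 0:
            raise ValueError("inverse-gamma hyperparameters must be positive")

    @property
    def n_stored(self) -> int:
        return self.iterations // self.thin


@dataclass
class PosteriorDraws:
    """Thinned stored samples for every block, variances and the deviance."""

    blocks: dict[str, np.ndarray]  # name -> (stored, dim)
    labels: dict[str, tuple[str, ...]]
    variances: dict[str, np.ndarray]  # name -> (stored,)
    deviance: np.ndarray
    eta_mean: np.ndarray
    config: MCMCConfig
    form: str = ""

    def __post_init__(self):
        counts = {a.shape[0] for a in self.blocks.values()}
        counts |= {a.shape[0] for a in self.variances.values()}
        counts.add(self.deviance.shape[0])
        if len(counts) != 1:
            raise ValueError("stored-draw counts differ across sample arrays")
        for name, arr in self.variances.items():
            if np.any(arr <= 0):
                raise ValueError(f"non-positive tau2 stored for block {name!r}")

    @property
    def n_stored(self) -> int:
        return self.deviance.shape[0]

    def scalar_parameters(self):
        """Yield (label, 1-D sample array) over every scalar parameter."""
        for name, arr in self.blocks.items():
            labs = self.labels.get(name) or tuple(f"{name}[{j}]" for j in range(arr.shape[1]))
            for j, lab in enumerate(labs):
                yield lab, arr[:, j]
        for name, arr in self.variances.items():
            yield f"tau2_{name}", arr


def draw_augmentation(eta: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One PG(1, eta_i) latent variable per observation."""
    seed = int(rng.integers(0, 2**31 - 1))
    return random_polya_gamma(eta, seed)


def block_conditional(
    design: np.ndarray,
    penalty: PenaltyMatrix | None,
    tau2: float | None,
    omega: np.ndarray,
    kappa: np.ndarray,
    eta_rest: np.ndarray,
):
    """Mean and Cholesky factor of the Gaussian full conditional.

    Q = X' diag(omega) X + K/tau2 and m = X'(kappa - omega * eta_rest);
    the conditional is Normal(Q^{-1} m, Q^{-1}).
    """
    q = (design * omega[:, None]).T @ design
    if penalty is not None:
        if tau2 is None or tau2 <= 0:
            raise ValueError("penalized block requires tau2 > 0")
        q = q + penalty.matrix / tau2
    m = design.T @ (kappa - omega * eta_rest)
    try:
        chol, lower = cho_factor(q, lower=True)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "singular conditional precision: the block design is collinear; "
            "drop a redundant column"
        ) from exc
    mean = cho_solve((chol, lower), m)
    return mean, np.tril(chol)


def update_block(
    y: np.ndarray,
    eta_rest: np.ndarray,
    design: np.ndarray,
    penalty: PenaltyMatrix | None,
    tau2: float | None,
    omega: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Exact draw of one coefficient block from its Gaussian conditional."""
    kappa = np.asarray(y, float) - 0.5
    mean, chol_l = block_conditional(design, penalty, tau2, omega, kappa, eta_rest)
    z = rng.standard_normal(len(mean))
    return mean + solve_triangular(chol_l.T, z, lower=False)


def update_variance(
    coef: np.ndarray, penalty: PenaltyMatrix, a: float, b: float, rng: np.random.Generator
) -> float:
    """tau2 ~ IG(a + rank(K)/2, b + coef'K coef / 2)."""
    if a <= 0 or b <= 0:
        raise ValueError("hyperparameters must be positive")
    shape = a + penalty.rank / 2.0
    rate = b + penalty.quadratic_form(coef) / 2.0
    return float(1.0 / rng.gamma(shape, 1.0 / rate))


def ig_posterior_params(coef, penalty, a, b) -> tuple[float, float]:
    """(shape, rate) of the tau2 full conditional; exposed for testing."""
    return a + penalty.rank / 2.0, b + penalty.quadratic_form(coef) / 2.0


def run_chain(spec: ModelSpec, y, config: MCMCConfig) -> PosteriorDraws:
    """Fit a ModelSpec by systematic-scan Gibbs; fully reproducible from seed."""
    y = np.asarray(y, dtype=float)
    if y.shape != (spec.n,):
        raise ValueError(f"response length {y.shape} does not match model n={spec.n}")
    if not np.all((y == 0.0) | (y == 1.0)):
        raise ValueError("response must be binary 0/1")
    if np.all(y == y[0]):
        warnings.warn(
            "degenerate response (all outcomes equal): estimates may be "
            "separated for unpenalized blocks",
            stacklevel=2,
        )
    rng = np.random.default_rng(config.seed)
    kappa = y - 0.5
    n = spec.n

    b0 = 0.0
    coefs = {t.name: np.zeros(t.dim) for t in spec.terms}
    contribs = {t.name: np.zeros(n) for t in spec.terms}
    tau2 = {t.name: 0.1 for t in spec.terms if t.penalized}
    eta = np.full(n, b0)

    n_stored = config.n_stored
    stored_blocks = {"intercept": np.empty((n_stored, 1))}
    stored_labels: dict[str, tuple[str, ...]] = {"intercept": ("intercept",)}
    for t in spec.terms:
        stored_blocks[t.name] = np.empty((n_stored, t.dim))
        stored_labels[t.name] = tuple(t.labels) if t.labels else tuple(
            f"{t.name}[{j}]" for j in range(t.dim)
        )
    stored_tau2 = {name: np.empty(n_stored) for name in tau2}
    dev_trace = np.empty(n_stored)
    eta_sum = np.zeros(n)

    total = config.burn_in + config.iterations
    store_at = 0
    for it in range(total):
        omega = draw_augmentation(eta, rng)

        # intercept (flat prior): scalar Gaussian conditional
        eta_rest = eta - b0
        prec = omega.sum()
        mean = float((kappa - omega * eta_rest).sum()) / prec
        b0 = mean + rng.standard_normal() / np.sqrt(prec)
        eta = eta_rest + b0

        for t in spec.terms:
            eta_rest = eta - contribs[t.name]
            theta = update_block(
                y, eta_rest, t.design, t.penalty, tau2.get(t.name), omega, rng
            )
            if t.penalized:
                # centre the block; its design rows sum to one, so the mean
                # shift is absorbed exactly by the intercept
                shift = float(theta.mean())
                theta = theta - shift
                b0 += shift
                eta_rest = eta_rest + shift
            coefs[t.name] = theta
            contribs[t.name] = t.design @ theta
            eta = eta_rest + contribs[t.name]

        for t in spec.terms:
            if t.penalized:
                a, b = t.hyper if t.hyper is not None else (config.a, config.b)
                tau2[t.name] = update_variance(coefs[t.name], t.penalty, a, b, rng)

        if not np.all(np.isfinite(eta)):
            raise RuntimeError(f"non-finite predictor at iteration {it}")

        k = it - config.burn_in + 1
        if k > 0 and k % config.thin == 0:
            stored_blocks["intercept"][store_at, 0] = b0
            for t in spec.terms:
                stored_blocks[t.name][store_at] = coefs[t.name]
            for name in tau2:
                stored_tau2[name][store_at] = tau2[name]
            dev_trace[store_at] = _deviance(y, eta)
            eta_sum += eta
            store_at += 1

    assert store_at == n_stored
    return PosteriorDraws(
        blocks=stored_blocks,
        labels=stored_labels,
        variances=stored_tau2,
        deviance=dev_trace,
        eta_mean=eta_sum / n_stored,
        config=config,
        form=spec.form,
    )


def autocorrelation(x: np.ndarray, max_lag: int = 50) -> np.ndarray | None:
    """Sample autocorrelation at lags 1..max_lag; None for a constant chain."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    xc = x - x.mean()
    denom = float(xc @ xc)
    if denom == 0.0:
        return None
    lags = min(max_lag, n - 1)
    return np.array([float(xc[: n - k] @ xc[k:]) / denom for k in range(1, lags + 1)])


def diagnostics(draws: PosteriorDraws, max_lag: int = 50) -> dict[str, dict]:
    """Trace and lag-k autocorrelation per scalar parameter.

    A constant chain has undefined autocorrelation; it is flagged rather
    than returned as NaN.
    """
    if draws.n_stored < 10:
        raise ValueError("need at least 10 stored draws for diagnostics")
    out: dict[str, dict] = {}
    for label, trace in draws.scalar_parameters():
        acf = autocorrelation(trace, max_lag)
        out[label] = {
            "trace": trace,
            "acf": acf,
            "constant": acf is None,
        }
    return out
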