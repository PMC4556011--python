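"""Synthetic DHS-style survey generator with known ground truth.

Real data of this kind (the Zimbabwe Demographic and Health Survey rounds)
are access-restricted, so this module generates tables with the same
statistical structure the analysis assumes: one row per child with a binary
two-week disease indicator, 13 binary categorical covariates, child's
current age (0-59 months), mother's age at the birth of her first child
(12-49 years) and a province label over a connected 10-province adjacency
graph. Outcomes are Bernoulli with logit equal to the geoadditive predictor
intercept + w'gamma + f_age(cca) + f_mab(mabfc) + f_str(s) + f_unstr(s),
and every generating component is retained in a :class:`SyntheticTruth` so
downstream fits can be scored against it.

All randomness flows from a single integer seed through
``numpy.random.SeedSequence.spawn``, one independent stream per stochastic
component, so tables are bit-reproducible.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .design import DEFAULT_CODINGS, encode_categorical
from .spatial import AdjacencyGraph, icar_precision, read_gra

__all__ = [
    "SyntheticTruth",
    "SimulationConfig",
    "SURVEY_PRESETS",
    "make_fixture_graph",
    "sample_icar_effect",
    "default_truth",
    "simulate_survey",
    "write_truth",
    "read_truth",
]

CONTINUOUS_COLUMNS = ("cca_months", "mabfc_years")
AGE_DOMAIN = (0.0, 59.0)
MAB_DOMAIN = (12.0, 49.0)

# Rough province population shares (city provinces heavier, Matabeleland
# lighter) emulating the unequal sampling density of the surveys.
DEFAULT_PROVINCE_WEIGHTS = np.array(
    [0.06, 0.16, 0.13, 0.09, 0.10, 0.11, 0.11, 0.06, 0.06, 0.12]
)

# Probability of the non-reference level per covariate, in DEFAULT_CODINGS
# order: plausible survey frequencies (e.g. ~51% male, ~32% urban, ~90%
# antenatal care and parental schooling).
DEFAULT_COVARIATE_FREQS = np.array(
    [0.51, 0.25, 0.32, 0.25, 0.45, 0.90, 0.70, 0.90, 0.70, 0.60, 0.90, 0.40, 0.85]
)

# Fixed-effect truths on the logit scale (odds ratios ~1.2-2), one per
# covariate. Together with the smooths these dominate the provincial
# effects, mirroring the effect hierarchy of the surveys being emulated.
DEFAULT_GAMMA = np.array(
    [0.30, 0.50, -0.60, 0.20, 0.40, -0.70, -0.50, -0.30, -0.40, -0.20, -0.24, 0.16, -0.36]
)

# Survey-like presets: (n children, outcome prevalence), matching the scale
# of the three survey rounds for the diarrhoea outcome.
SURVEY_PRESETS: dict[str, tuple[int, float]] = {
    "1999": (3162, 436 / 3162),
    "2005-6": (4738, 614 / 4738),
    "2010-11": (5055, 674 / 5055),
}


def _bump_f_age(amplitude: float = 1.0) -> Callable[[np.ndarray], np.ndarray]:
    """Localized risk bump peaking near 12-13 months, centred to mean zero.

    Emulates the weaning-age pattern: risk rises through infancy, peaks
    shortly after the first year, drops sharply by ~20 months and varies
    little for older children.
    """
    grid = np.arange(AGE_DOMAIN[0], AGE_DOMAIN[1] + 1)
    raw = lambda x: amplitude * np.exp(-0.5 * ((np.asarray(x, float) - 13.0) / 5.0) ** 2)
    offset = raw(grid).mean()
    return lambda x: raw(x) - offset


def _decreasing_f_mab(amplitude: float = 0.8) -> Callable[[np.ndarray], np.ndarray]:
    """Monotone decreasing effect of mother's age at first birth, centred."""
    grid = np.arange(MAB_DOMAIN[0], MAB_DOMAIN[1] + 1)
    raw = lambda x: amplitude / (1.0 + np.exp((np.asarray(x, float) - 26.0) / 3.5))
    offset = raw(grid).mean()
    return lambda x: raw(x) - offset


@dataclass
class SyntheticTruth:
    """Generating parameters kept alongside a simulated table."""

    intercept: float
    gamma: np.ndarray
    f_age: Callable[[np.ndarray], np.ndarray]
    f_mab: Callable[[np.ndarray], np.ndarray]
    spatial_str: np.ndarray
    spatial_unstr: np.ndarray
    tau2_str: float
    tau2_unstr: float

    def __post_init__(self):
        self.gamma = np.asarray(self.gamma, dtype=float)
        self.spatial_str = np.asarray(self.spatial_str, dtype=float)
        self.spatial_unstr = np.asarray(self.spatial_unstr, dtype=float)
        if abs(self.spatial_str.sum()) > 1e-8:
            raise ValueError("structured spatial truth must sum to zero")
        for f, dom in ((self.f_age, AGE_DOMAIN), (self.f_mab, MAB_DOMAIN)):
            vals = f(np.linspace(*dom, 25))
            if not np.all(np.isfinite(vals)):
                raise ValueError("truth smooth evaluates to non-finite values on its domain")
        if self.tau2_str <= 0 or self.tau2_unstr < 0:
            raise ValueError("truth variance parameters must be positive")


@dataclass(frozen=True)
class SimulationConfig:
    """Size, prevalence target, seed and covariate frequencies of one survey."""

    n: int
    graph: AdjacencyGraph
    seed: int = 0
    prevalence_target: float = 0.133
    covariate_freqs: np.ndarray = field(
        default_factory=lambda: DEFAULT_COVARIATE_FREQS.copy()
    )
    province_weights: np.ndarray | None = None

    def __post_init__(self):
        freqs = np.asarray(self.covariate_freqs, dtype=float)
        object.__setattr__(self, "covariate_freqs", freqs)
        if freqs.shape != (len(DEFAULT_CODINGS),):
            raise ValueError(f"need {len(DEFAULT_CODINGS)} covariate frequencies")
        if np.any(freqs <= 0.0) or np.any(freqs >= 1.0):
            raise ValueError("covariate frequencies must lie strictly in (0, 1)")
        if not 0.0 < self.prevalence_target < 1.0:
            raise ValueError("prevalence target must lie in (0, 1)")
        if self.n < self.graph.n_regions:
            raise ValueError("n must be at least the number of provinces")
        if self.province_weights is not None:
            w = np.asarray(self.province_weights, dtype=float)
            if w.shape != (self.graph.n_regions,) or np.any(w <= 0):
                raise ValueError("province weights must be positive, one per region")
            object.__setattr__(self, "province_weights", w / w.sum())


def make_fixture_graph() -> AdjacencyGraph:
    """The packaged connected 10-province adjacency graph."""
    ref = importlib.resources.files("geoadd.data").joinpath("zimbabwe10.gra")
    with importlib.resources.as_file(ref) as path:
        return read_gra(path)


def sample_icar_effect(graph: AdjacencyGraph, tau2: float, seed) -> np.ndarray:
    """One centred draw from the intrinsic CAR prior on the graph.

    Sampling happens in the non-null eigenspace of the ICAR precision
    (1/tau2) * (diag(degree) - adjacency) and the draw is centred, so the
    output sums to zero exactly (to floating precision).
    """
    if tau2 <= 0:
        raise ValueError("tau2 must be positive")
    graph.require_connected()
    k = icar_precision(graph).matrix
    evals, evecs = np.linalg.eigh(k)
    keep = evals > 1e-10
    rng = np.random.default_rng(seed)
    z = rng.standard_normal(int(keep.sum()))
    f = evecs[:, keep] @ (z * np.sqrt(tau2 / evals[keep]))
    return f - f.mean()


def default_truth(
    graph: AdjacencyGraph,
    seed: int = 0,
    prevalence_target: float | None = 0.133,
    gamma: np.ndarray | None = None,
    age_amplitude: float = 1.0,
    mab_amplitude: float = 0.8,
    tau2_str: float = 0.15,
    tau2_unstr: float = 0.1,
) -> SyntheticTruth:
    """Strong-signal generating truth: bump-shaped age effect, decreasing
    mother's-age effect, ICAR structured and small i.i.d. unstructured
    spatial effects, modest fixed effects.

    When ``prevalence_target`` is given the intercept is calibrated by
    root-finding on a large covariate simulation so the marginal outcome
    prevalence matches the target.
    """
    ss = np.random.SeedSequence(seed).spawn(3)
    truth = SyntheticTruth(
        intercept=0.0,
        gamma=DEFAULT_GAMMA.copy() if gamma is None else np.asarray(gamma, float),
        f_age=_bump_f_age(age_amplitude),
        f_mab=_decreasing_f_mab(mab_amplitude),
        spatial_str=sample_icar_effect(graph, tau2_str, ss[0]),
        spatial_unstr=np.random.default_rng(ss[1]).normal(0.0, np.sqrt(tau2_unstr), graph.n_regions)
        if tau2_unstr > 0
        else np.zeros(graph.n_regions),
        tau2_str=tau2_str,
        tau2_unstr=tau2_unstr,
    )
    if prevalence_target is not None:
        calib_cfg = SimulationConfig(
            n=20000, graph=graph, seed=int(ss[2].generate_state(1)[0] % 2**31),
            prevalence_target=prevalence_target,
        )
        rest = _predictor_without_intercept(calib_cfg, truth)
        truth.intercept = float(
            brentq(lambda b0: expit(b0 + rest).mean() - prevalence_target, -15.0, 15.0)
        )
    return truth


def _draw_covariates(config: SimulationConfig, rng_streams) -> pd.DataFrame:
    (r_cat, r_age, r_mab, r_prov) = rng_streams
    n = config.n
    data = {}
    for coding, freq, stream in zip(DEFAULT_CODINGS, config.covariate_freqs, r_cat):
        flags = np.random.default_rng(stream).random(n) < freq
        data[coding.covariate] = np.where(flags, coding.nonreference, coding.reference)
    data["cca_months"] = np.random.default_rng(r_age).integers(0, 60, size=n)
    # Discretized Gamma shifted to 12 years: shape 5, scale 2 => mode ~20.
    mab = 12.0 + np.random.default_rng(r_mab).gamma(5.0, 2.0, size=n)
    data["mabfc_years"] = np.clip(np.round(mab), MAB_DOMAIN[0], MAB_DOMAIN[1])
    weights = (
        config.province_weights
        if config.province_weights is not None
        else DEFAULT_PROVINCE_WEIGHTS[: config.graph.n_regions]
        / DEFAULT_PROVINCE_WEIGHTS[: config.graph.n_regions].sum()
    )
    prov_idx = np.random.default_rng(r_prov).choice(config.graph.n_regions, size=n, p=weights)
    data["province"] = np.asarray(config.graph.labels)[prov_idx]
    return pd.DataFrame(data)


def _streams(config: SimulationConfig):
    root = np.random.SeedSequence(config.seed)
    cat_root, r_age, r_mab, r_prov, r_out = root.spawn(5)
    return (cat_root.spawn(len(DEFAULT_CODINGS)), r_age, r_mab, r_prov), r_out


def _eta(table: pd.DataFrame, truth: SyntheticTruth, graph: AdjacencyGraph) -> np.ndarray:
    w = encode_categorical(table, DEFAULT_CODINGS)
    prov_idx = np.array([graph.index_of(p) for p in table["province"]])
    return (
        truth.intercept
        + w @ truth.gamma
        + truth.f_age(table["cca_months"].to_numpy(float))
        + truth.f_mab(table["mabfc_years"].to_numpy(float))
        + truth.spatial_str[prov_idx]
        + truth.spatial_unstr[prov_idx]
    )


def _predictor_without_intercept(config, truth):
    cov_streams, _ = _streams(config)
    table = _draw_covariates(config, cov_streams)
    return _eta(table, truth, config.graph) - truth.intercept


def simulate_survey(
    config: SimulationConfig, truth: SyntheticTruth
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Simulate one survey table; outcomes are Bernoulli(expit(eta)).

    Returns the table (outcome, 13 covariate columns, cca_months,
    mabfc_years, province) and echoes the generating truth. Identical config
    (including seed) and truth give an identical table.
    """
    if len(truth.spatial_str) != config.graph.n_regions:
        raise ValueError("truth spatial effects do not match the graph size")
    cov_streams, r_out = _streams(config)
    table = _draw_covariates(config, cov_streams)
    eta = _eta(table, truth, config.graph)
    y = (np.random.default_rng(r_out).random(config.n) < expit(eta)).astype(int)
    table.insert(0, "outcome", y)
    return table, truth


def write_truth(truth: SyntheticTruth, graph: AdjacencyGraph, path) -> None:
    """Flat key/value serialization (smooths stored on integer grids)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"intercept = {float(truth.intercept)!r}\n")
        fh.write(f"tau2_str = {float(truth.tau2_str)!r}\n")
        fh.write(f"tau2_unstr = {float(truth.tau2_unstr)!r}\n")
        for coding, g in zip(DEFAULT_CODINGS, truth.gamma):
            fh.write(f"gamma.{coding.covariate} = {float(g)!r}\n")
        for label, s, u in zip(graph.labels, truth.spatial_str, truth.spatial_unstr):
            fh.write(f"spatial_str.{label} = {float(s)!r}\n")
            fh.write(f"spatial_unstr.{label} = {float(u)!r}\n")
        for x in np.arange(AGE_DOMAIN[0], AGE_DOMAIN[1] + 1):
            fh.write(f"f_age.{int(x)} = {float(truth.f_age(x))}\n")
        for x in np.arange(MAB_DOMAIN[0], MAB_DOMAIN[1] + 1):
            fh.write(f"f_mab.{int(x)} = {float(truth.f_mab(x))}\n")


def read_truth(path) -> dict[str, float]:
    out: dict[str, float] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("=")
            out[key.strip()] = float(value)
    return out
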