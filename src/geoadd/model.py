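"""Likelihood and the four nested predictor forms.

The response is Bernoulli with logit link: f(y_i | eta_i) =
exp(y_i eta_i - log(1 + exp(eta_i))). Four predictor configurations are
fitted and compared by DIC:

* ``M0`` — strictly linear: intercept + 13 reference-coded categorical
  covariates + the two continuous covariates entered linearly (standardized),
* ``M1`` — intercept + structured (ICAR) provincial effect only,
* ``M2`` — intercept + P-spline smooths of child's age and mother's age at
  first birth + unstructured (i.i.d.) provincial effect + the reduced
  8-covariate linear block u,
* ``M3`` — intercept + both smooths + structured provincial effect + the
  full 13-covariate linear block z.

``CONV`` (M3 plus an additional i.i.d. provincial effect, the Besag-York-
Mollie convolution) exists for the hyperprior sensitivity analysis, which
reports both spatial variance parameters.

Fixed-effect blocks (intercept, linear coefficients) carry improper flat
priors; penalized blocks carry Gaussian priors with precision K/tau2 and an
inverse-gamma IG(a, b) hyperprior on each tau2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import (
    DEFAULT_CODINGS,
    REDUCED_COVARIATES,
    PenaltyMatrix,
    SplineBasisSpec,
    bspline_basis,
    encode_categorical,
)
from .spatial import AdjacencyGraph, icar_precision

__all__ = [
    "MODEL_FORMS",
    "Term",
    "ModelSpec",
    "ModelState",
    "log_likelihood",
    "build_model",
    "predictor",
]

MODEL_FORMS = ("M0", "M1", "M2", "M3", "CONV")


@dataclass
class Term:
    """One additive block of the predictor: design matrix plus optional penalty."""

    kind: str  # linear_block | pspline | mrf | iid_region
    name: str
    design: np.ndarray
    penalty: PenaltyMatrix | None = None
    hyper: tuple[float, float] | None = None
    labels: tuple[str, ...] = ()
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.design = np.asarray(self.design, dtype=float)
        if self.design.ndim != 2:
            raise ValueError("term design must be a 2-D matrix")
        if self.penalty is not None and self.penalty.dim != self.design.shape[1]:
            raise ValueError(f"term {self.name}: penalty/design dimension mismatch")

    @property
    def dim(self) -> int:
        return self.design.shape[1]

    @property
    def penalized(self) -> bool:
        return self.penalty is not None


@dataclass
class ModelSpec:
    """An assemblable term collection for one predictor form."""

    form: str
    terms: list[Term]
    n: int

    def term(self, name: str) -> Term:
        for t in self.terms:
            if t.name == name:
                return t
        raise KeyError(f"model has no term named {name!r}")

    @property
    def term_names(self) -> tuple[str, ...]:
        return tuple(t.name for t in self.terms)


@dataclass
class ModelState:
    """Intercept plus per-term coefficient vectors; eta is their sum."""

    spec: ModelSpec
    intercept: float = 0.0
    coefs: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        for t in self.spec.terms:
            if t.name not in self.coefs:
                self.coefs[t.name] = np.zeros(t.dim)
            elif len(self.coefs[t.name]) != t.dim:
                raise ValueError(f"coefficient block {t.name!r} has wrong dimension")


def log_likelihood(y, eta) -> float:
    """Bernoulli-logit log likelihood sum_i [y_i eta_i - log(1 + e^eta_i)].

    Computed with log1p/softplus branching so |eta| up to ~700 is safe.
    """
    y = np.asarray(y, dtype=float)
    eta = np.asarray(eta, dtype=float)
    if y.shape != eta.shape:
        raise ValueError(f"length mismatch: y has {y.shape}, eta has {eta.shape}")
    if not np.all((y == 0.0) | (y == 1.0)):
        raise ValueError("response must be binary 0/1")
    # log(1 + exp(eta)) = max(eta, 0) + log1p(exp(-|eta|))
    softplus = np.maximum(eta, 0.0) + np.log1p(np.exp(-np.abs(eta)))
    return float(np.sum(y * eta - softplus))


def deviance(y, eta) -> float:
    return -2.0 * log_likelihood(y, eta)


def _linear_term(data: pd.DataFrame, covariates, include_continuous: bool) -> Term:
    codings = [c for c in DEFAULT_CODINGS if c.covariate in set(covariates)]
    missing = [c.covariate for c in codings if c.covariate not in data.columns]
    if missing:
        raise KeyError(f"data lacks covariate columns: {missing}")
    design = encode_categorical(data, codings)
    labels = [c.covariate for c in codings]
    meta: dict = {"codings": tuple(codings)}
    if include_continuous:
        cont = []
        scale_info = {}
        for col in ("cca_months", "mabfc_years"):
            x = data[col].to_numpy(float)
            mu, sd = float(x.mean()), float(x.std())
            sd = sd if sd > 0 else 1.0
            cont.append((x - mu) / sd)
            labels.append(f"{col}_std")
            scale_info[col] = (mu, sd)
        design = np.column_stack([design] + cont)
        meta["standardization"] = scale_info
    return Term("linear_block", "linear", design, labels=tuple(labels), meta=meta)


def _pspline_term(data, column, name, hyper, degree, intervals, order) -> Term:
    x = data[column].to_numpy(float)
    lo, hi = float(x.min()), float(x.max())
    if hi <= lo:
        raise ValueError(f"continuous covariate {column!r} is constant")
    spec = SplineBasisSpec(degree=degree, interior_intervals=intervals, domain=(lo, hi), penalty_order=order)
    basis = bspline_basis(x, spec)
    labels = tuple(f"{name}[{j}]" for j in range(spec.dimension))
    return Term("pspline", name, basis, spec.penalty(), hyper, labels, {"spec": spec, "column": column})


def _province_incidence(data: pd.DataFrame, graph: AdjacencyGraph) -> np.ndarray:
    idx = np.array([graph.index_of(p) for p in data["province"]])
    z = np.zeros((len(idx), graph.n_regions))
    z[np.arange(len(idx)), idx] = 1.0
    return z


def build_model(
    form: str,
    data: pd.DataFrame,
    graph: AdjacencyGraph | None = None,
    hyper: tuple[float, float] = (0.001, 0.001),
    spline_degree: int = 3,
    spline_intervals: int = 20,
    penalty_order: int = 2,
) -> ModelSpec:
    """Assemble the term collection for one of the forms in MODEL_FORMS."""
    if form not in MODEL_FORMS:
        raise ValueError(f"unknown model form {form!r}; expected one of {MODEL_FORMS}")
    needs_graph = form != "M0"
    if needs_graph:
        if graph is None:
            raise ValueError(f"form {form} includes a spatial term and needs a graph")
        graph.require_connected()
    terms: list[Term] = []
    full = tuple(c.covariate for c in DEFAULT_CODINGS)

    if form == "M0":
        terms.append(_linear_term(data, full, include_continuous=True))
    elif form == "M1":
        pass  # intercept + structured spatial only
    elif form == "M2":
        terms.append(_linear_term(data, REDUCED_COVARIATES, include_continuous=False))
    else:  # M3, CONV
        terms.append(_linear_term(data, full, include_continuous=False))

    if form in ("M2", "M3", "CONV"):
        terms.append(
            _pspline_term(data, "cca_months", "f_cca", hyper, spline_degree, spline_intervals, penalty_order)
        )
        terms.append(
            _pspline_term(data, "mabfc_years", "f_mabfc", hyper, spline_degree, spline_intervals, penalty_order)
        )

    if form in ("M1", "M3", "CONV"):
        z = _province_incidence(data, graph)
        terms.append(
            Term("mrf", "spatial_str", z, icar_precision(graph), hyper, graph.labels, {"graph": graph})
        )
    if form in ("M2", "CONV"):
        z = _province_incidence(data, graph)
        iid_pen = PenaltyMatrix(np.eye(graph.n_regions), rank=graph.n_regions, null_space_dim=0)
        terms.append(
            Term("iid_region", "spatial_unstr", z, iid_pen, hyper, graph.labels, {"graph": graph})
        )
    return ModelSpec(form=form, terms=terms, n=len(data))


def predictor(state: ModelState) -> np.ndarray:
    """eta = intercept + sum of term design @ coefficient contributions."""
    eta = np.full(state.spec.n, state.intercept)
    for t in state.spec.terms:
        coef = state.coefs[t.name]
        if len(coef) != t.dim:
            raise ValueError(f"dimension mismatch in block {t.name!r}")
        eta = eta + t.design @ coef
    return eta
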