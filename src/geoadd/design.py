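"""Design and penalty matrices.

Three building blocks of the geoadditive predictor live here:

* reference coding of the 13 binary categorical covariates (one 0/1 column
  per covariate, 1 = non-reference level),
* equidistant-knot B-spline bases for the two continuous covariates
  (child's current age in months, mother's age at birth of first child in
  years), and
* random-walk difference penalties K = D'D that turn the B-spline
  coefficients into a P-spline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline

__all__ = [
    "CategoricalCoding",
    "DEFAULT_CODINGS",
    "REDUCED_COVARIATES",
    "PenaltyMatrix",
    "SplineBasisSpec",
    "encode_categorical",
    "bspline_basis",
    "difference_penalty",
    "write_codings",
    "read_codings",
]


@dataclass(frozen=True)
class CategoricalCoding:
    """Reference coding of one binary covariate."""

    covariate: str
    reference: str
    nonreference: str


# Column order and reference levels follow the standard DHS questionnaire
# covariates; the first-listed category of each is the reference.
DEFAULT_CODINGS: tuple[CategoricalCoding, ...] = (
    CategoricalCoding("sex_of_child", "Female", "Male"),
    CategoricalCoding("preceding_birth_interval", "25+ months", "<25 months"),
    CategoricalCoding("place_of_residence", "Rural", "Urban"),
    CategoricalCoding("marital_status", "Married", "Single"),
    CategoricalCoding("household_size", "Small", "Medium and/or large"),
    CategoricalCoding("antenatal_visit", "No visits", "Had some visits"),
    CategoricalCoding("place_of_delivery", "Home and others", "Hospital"),
    CategoricalCoding("mothers_education", "No education", "Primary, Secondary or Higher education"),
    CategoricalCoding("source_of_drinking_water", "Unprotected source", "Protected Source"),
    CategoricalCoding("type_of_toilet_facilities", "No facility", "Pit or flush"),
    CategoricalCoding("partners_education", "No education", "Primary, Secondary or Higher education"),
    CategoricalCoding("exposure_to_mass_media", "No Radio", "Yes Radio"),
    CategoricalCoding("ever_had_vaccination", "No", "Yes"),
)

# The reduced covariate vector u drops both education variables, toilet type,
# mass-media exposure and water source from the full vector z (13 -> 8).
_DROPPED_IN_REDUCED = frozenset(
    {
        "mothers_education",
        "partners_education",
        "type_of_toilet_facilities",
        "exposure_to_mass_media",
        "source_of_drinking_water",
    }
)
REDUCED_COVARIATES: tuple[str, ...] = tuple(
    c.covariate for c in DEFAULT_CODINGS if c.covariate not in _DROPPED_IN_REDUCED
)


@dataclass(frozen=True)
class PenaltyMatrix:
    """Symmetric PSD penalty K with its rank and null-space dimension."""

    matrix: np.ndarray
    rank: int
    null_space_dim: int

    def __post_init__(self):
        k = np.asarray(self.matrix, dtype=float)
        if k.ndim != 2 or k.shape[0] != k.shape[1]:
            raise ValueError("penalty matrix must be square")
        if not np.allclose(k, k.T, atol=1e-10):
            raise ValueError("penalty matrix must be symmetric")
        object.__setattr__(self, "matrix", k)

    @property
    def dim(self) -> int:
        return self.matrix.shape[0]

    def quadratic_form(self, coef: np.ndarray) -> float:
        coef = np.asarray(coef, dtype=float)
        return float(coef @ self.matrix @ coef)


@dataclass(frozen=True)
class SplineBasisSpec:
    """Equidistant-knot B-spline basis: dimension = interior_intervals + degree."""

    degree: int = 3
    interior_intervals: int = 20
    domain: tuple[float, float] = (0.0, 1.0)
    penalty_order: int = 2

    def __post_init__(self):
        if self.degree < 1:
            raise ValueError("spline degree must be >= 1")
        if self.interior_intervals < 1:
            raise ValueError("need at least one interior interval")
        lo, hi = self.domain
        if not hi > lo:
            raise ValueError("domain upper bound must exceed lower bound")
        if self.penalty_order not in (1, 2):
            raise ValueError("penalty order must be 1 or 2")
        if self.dimension <= self.penalty_order:
            raise ValueError("basis dimension must exceed the penalty order")

    @property
    def dimension(self) -> int:
        return self.interior_intervals + self.degree

    def knots(self) -> np.ndarray:
        """Full knot vector: equidistant, extended by ``degree`` knots each side."""
        lo, hi = self.domain
        h = (hi - lo) / self.interior_intervals
        return lo + h * np.arange(-self.degree, self.interior_intervals + self.degree + 1)

    def penalty(self) -> PenaltyMatrix:
        return difference_penalty(self.dimension, self.penalty_order)


def encode_categorical(
    table: pd.DataFrame, codings: tuple[CategoricalCoding, ...] | list[CategoricalCoding] = DEFAULT_CODINGS
) -> np.ndarray:
    """Reference-code categorical covariates into an n x r 0/1 matrix.

    Column j is 1 iff the record holds the non-reference level of covariate j;
    column order is the order of ``codings``. A value matching neither level
    is an error naming the record and covariate.
    """
    cols = []
    for coding in codings:
        if coding.covariate not in table.columns:
            raise KeyError(f"table lacks covariate column {coding.covariate!r}")
        values = table[coding.covariate].to_numpy()
        is_non = values == coding.nonreference
        is_ref = values == coding.reference
        bad = ~(is_non | is_ref)
        if bad.any():
            i = int(np.flatnonzero(bad)[0])
            raise ValueError(
                f"record {table.index[i]} has unseen level {values[i]!r} for "
                f"covariate {coding.covariate!r} (expected {coding.reference!r} "
                f"or {coding.nonreference!r})"
            )
        cols.append(is_non.astype(float))
    return np.column_stack(cols)


def bspline_basis(x, spec: SplineBasisSpec) -> np.ndarray:
    """Evaluate the B-spline basis at ``x`` (Cox-de Boor via scipy).

    Rows sum to one everywhere on the domain (partition of unity); values
    outside ``spec.domain`` raise rather than extrapolate.
    """
    x = np.asarray(x, dtype=float)
    lo, hi = spec.domain
    if np.any(x < lo) or np.any(x > hi):
        bad = x[(x < lo) | (x > hi)][0]
        raise ValueError(f"value {bad} outside spline domain [{lo}, {hi}]")
    t = spec.knots()
    # design_matrix treats the base interval as half-open; fold x == hi into
    # the last interval so the right endpoint evaluates instead of erroring.
    eps = (hi - lo) * 1e-12
    xq = np.where(x >= hi, hi - eps, x)
    b = BSpline.design_matrix(xq, t, spec.degree, extrapolate=False).toarray()
    return b


def difference_penalty(n_coef: int, order: int) -> PenaltyMatrix:
    """Random-walk penalty K = D'D with D the order-th difference operator."""
    if order < 1:
        raise ValueError("difference order must be >= 1")
    if order >= n_coef:
        raise ValueError(f"difference order {order} must be < number of coefficients {n_coef}")
    d = np.diff(np.eye(n_coef), n=order, axis=0)
    return PenaltyMatrix(matrix=d.T @ d, rank=n_coef - order, null_space_dim=order)


def write_codings(codings, path) -> None:
    pd.DataFrame(
        [(c.covariate, c.reference, c.nonreference) for c in codings],
        columns=["covariate", "reference", "nonreference"],
    ).to_csv(path, index=False)


def read_codings(path) -> tuple[CategoricalCoding, ...]:
    df = pd.read_csv(path)
    return tuple(
        CategoricalCoding(r.covariate, r.reference, r.nonreference) for r in df.itertuples()
    )
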