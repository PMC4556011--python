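"""scikit-learn style estimator wrapping the geoadditive logistic model.

``GeoadditiveLogisticRegression`` is a Bayesian classifier: ``fit`` runs the
Pólya-Gamma Gibbs sampler for the requested predictor form and exposes the
posterior through fitted attributes; ``predict_proba`` evaluates the
posterior-mean predictor on new rows. It follows the sklearn estimator
contract (``get_params``/``set_params``, trailing-underscore fitted
attributes, ``clone``-compatible constructor), so it composes with sklearn
model-selection utilities that can pass through DataFrame inputs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.base import BaseEstimator, ClassifierMixin

from .inference import compute_dic, summarize
from .mcmc import MCMCConfig, run_chain
from .model import build_model
from .spatial import AdjacencyGraph

__all__ = ["GeoadditiveLogisticRegression"]


class GeoadditiveLogisticRegression(ClassifierMixin, BaseEstimator):
    """Bayesian geoadditive logistic regression fitted by Gibbs sampling.

    Parameters
    ----------
    form : {"M0", "M1", "M2", "M3", "CONV"}, default "M3"
        Predictor configuration; see :mod:`geoadd.model`.
    graph : AdjacencyGraph or None
        Province adjacency; required for every form except M0.
    burn_in, iterations, thin : int
        Chain schedule (iterations counts post-burn-in sweeps).
    a, b : float
        Inverse-gamma hyperparameters of every variance parameter.
    spline_degree, spline_intervals, penalty_order : int
        P-spline basis and random-walk penalty settings.
    random_state : int, default 0
        Seed for the whole chain.

    Attributes
    ----------
    draws_ : PosteriorDraws
    summary_ : DataFrame of posterior means/SDs/quantiles per parameter.
    dic_ : DICReport
    intercept_ : posterior mean intercept.
    coef_ : posterior mean of the linear block (empty for M1).
    spatial_effects_ : DataFrame (region, mean, sd, q2.5, q97.5) or None.
    """

    def __init__(
        self,
        form: str = "M3",
        graph: AdjacencyGraph | None = None,
        burn_in: int = 1000,
        iterations: int = 4000,
        thin: int = 4,
        a: float = 0.001,
        b: float = 0.001,
        spline_degree: int = 3,
        spline_intervals: int = 20,
        penalty_order: int = 2,
        random_state: int = 0,
    ):
        self.form = form
        self.graph = graph
        self.burn_in = burn_in
        self.iterations = iterations
        self.thin = thin
        self.a = a
        self.b = b
        self.spline_degree = spline_degree
        self.spline_intervals = spline_intervals
        self.penalty_order = penalty_order
        self.random_state = random_state

    def fit(self, X: pd.DataFrame, y):
        if not isinstance(X, pd.DataFrame):
            raise TypeError("X must be a DataFrame with named covariate columns")
        y = np.asarray(y)
        if len(y) != len(X):
            raise ValueError("X and y have different lengths")
        self.classes_ = np.array([0, 1])
        self.spec_ = build_model(
            self.form,
            X,
            self.graph,
            hyper=(self.a, self.b),
            spline_degree=self.spline_degree,
            spline_intervals=self.spline_intervals,
            penalty_order=self.penalty_order,
        )
        config = MCMCConfig(
            burn_in=self.burn_in,
            iterations=self.iterations,
            thin=self.thin,
            seed=self.random_state,
            a=self.a,
            b=self.b,
        )
        self.draws_ = run_chain(self.spec_, y, config)
        self.summary_ = summarize(self.draws_)
        self.dic_ = compute_dic(self.draws_, y)
        self.intercept_ = float(self.draws_.blocks["intercept"].mean())
        self.n_features_in_ = X.shape[1]
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)

        self._post_means = {
            name: arr.mean(axis=0) for name, arr in self.draws_.blocks.items()
        }
        if "linear" in self.draws_.blocks:
            self.coef_ = self._post_means["linear"]
        else:
            self.coef_ = np.empty(0)
        self.spatial_effects_ = self._spatial_table()
        return self

    def _spatial_table(self) -> pd.DataFrame | None:
        name = "spatial_str" if "spatial_str" in self.draws_.blocks else (
            "spatial_unstr" if "spatial_unstr" in self.draws_.blocks else None
        )
        if name is None:
            return None
        arr = self.draws_.blocks[name]
        labels = self.draws_.labels[name]
        return pd.DataFrame(
            {
                "region": labels,
                "mean": arr.mean(axis=0),
                "sd": arr.std(axis=0, ddof=1),
                "q2.5": np.percentile(arr, 2.5, axis=0),
                "q97.5": np.percentile(arr, 97.5, axis=0),
            }
        )

    def decision_function(self, X: pd.DataFrame) -> np.ndarray:
        """Posterior-mean linear predictor evaluated on new rows."""
        self._check_fitted()
        from .design import bspline_basis, encode_categorical

        eta = np.full(len(X), self.intercept_)
        for t in self.spec_.terms:
            mean_coef = self._post_means[t.name]
            if t.kind == "linear_block":
                design = encode_categorical(X, t.meta["codings"])
                if "standardization" in t.meta:
                    cont = []
                    for col, (mu, sd) in t.meta["standardization"].items():
                        cont.append((X[col].to_numpy(float) - mu) / sd)
                    design = np.column_stack([design] + cont)
            elif t.kind == "pspline":
                design = bspline_basis(X[t.meta["column"]].to_numpy(float), t.meta["spec"])
            else:  # mrf / iid_region
                graph = t.meta["graph"]
                idx = np.array([graph.index_of(p) for p in X["province"]])
                design = np.zeros((len(X), graph.n_regions))
                design[np.arange(len(X)), idx] = 1.0
            eta = eta + design @ mean_coef
        return eta

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        p1 = expit(self.decision_function(X))
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return (self.decision_function(X) > 0.0).astype(int)

    def _check_fitted(self):
        if not hasattr(self, "draws_"):
            raise AttributeError("estimator is not fitted; call fit first")
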