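"""Posterior summarization, DIC and model comparison.

DIC = Dbar + pD with Dbar the posterior mean of the deviance -2 log L and
pD = Dbar - D(eta_bar) the effective number of parameters, where eta_bar is
the posterior mean of the additive predictor (plugging in the mean of eta
rather than of the coefficients keeps the plug-in invariant to the block
centring convention). Smaller DIC is preferred; a model within 3 DIC units
of the best cannot be distinguished from it, differences of 3-7 are weak
evidence, and larger differences are considered decisive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mcmc import PosteriorDraws
from .model import deviance as _deviance

__all__ = ["DICReport", "summarize", "compute_dic", "compare_models", "delta_dic_verdict"]


@dataclass(frozen=True)
class DICReport:
    dbar: float
    d_at_mean: float

    @property
    def pd(self) -> float:
        return self.dbar - self.d_at_mean

    @property
    def dic(self) -> float:
        return self.dbar + self.pd


def summarize(draws: PosteriorDraws) -> pd.DataFrame:
    """Mean, SD, median and central 95% interval per scalar parameter.

    Quantiles interpolate linearly between order statistics (numpy's
    ``linear`` rule); SD uses the n-1 denominator.
    """
    if draws.n_stored < 2:
        raise ValueError("need at least 2 stored draws to summarize")
    rows = []
    for label, x in draws.scalar_parameters():
        rows.append(
            {
                "parameter": label,
                "mean": float(np.mean(x)),
                "sd": float(np.std(x, ddof=1)),
                "median": float(np.median(x)),
                "q2.5": float(np.percentile(x, 2.5)),
                "q97.5": float(np.percentile(x, 97.5)),
            }
        )
    return pd.DataFrame(rows).set_index("parameter")


def summarize_chain(x: np.ndarray) -> dict[str, float]:
    """Summary of a single 1-D chain under the same conventions."""
    x = np.asarray(x, dtype=float)
    return {
        "mean": float(np.mean(x)),
        "sd": float(np.std(x, ddof=1)) if len(x) > 1 else 0.0,
        "median": float(np.median(x)),
        "q2.5": float(np.percentile(x, 2.5)),
        "q97.5": float(np.percentile(x, 97.5)),
    }


def compute_dic(draws: PosteriorDraws, y) -> DICReport:
    """DIC from the stored deviance trace and the posterior mean of eta."""
    dbar = float(np.mean(draws.deviance))
    d_at_mean = _deviance(np.asarray(y, float), draws.eta_mean)
    report = DICReport(dbar=dbar, d_at_mean=d_at_mean)
    if report.pd < 0:
        warnings.warn(
            f"negative effective number of parameters (pD = {report.pd:.3f}); "
            "the deviance is not convex along the chain path",
            stacklevel=2,
        )
    return report


def delta_dic_verdict(delta: float) -> str:
    """Classify a DIC difference against the best model.

    Strictly below 3 the models cannot be distinguished; from 3 up to and
    including 7 the evidence is weak; above 7 the models are distinguishable
    (exact boundary values fall into the weaker category).
    """
    if delta < 0:
        raise ValueError("delta DIC against the best model cannot be negative")
    if delta < 3.0:
        return "indistinguishable"
    if delta <= 7.0:
        return "weak"
    return "distinguishable"


def compare_models(reports: list[tuple[str, DICReport]]) -> pd.DataFrame:
    """Rank models by DIC ascending and classify each gap to the best model."""
    if len(reports) < 1:
        raise ValueError("need at least one model report")
    rows = [
        {"model": form, "deviance": r.dbar, "pD": r.pd, "DIC": r.dic}
        for form, r in reports
    ]
    df = pd.DataFrame(rows).sort_values("DIC", kind="stable").reset_index(drop=True)
    best = df["DIC"].iloc[0]
    df["delta_DIC"] = df["DIC"] - best
    df["verdict"] = [
        "best" if i == 0 else delta_dic_verdict(d) for i, d in enumerate(df["delta_DIC"])
    ]
    df["best"] = df.index == 0
    return df
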