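"""Gaussian-model driverness scores for FDR-bearing entities.

Each entity (mutation, gene or pathway) carries an FDR; the score of an
entity is the standard normal cumulative probability of its
x = -log2(FDR) after Z-transformation against the population of x
values in its own entity class within one cohort:

    score_i = Phi((x_i - mu) / sigma)

A higher score (in (0, 1)) means a smaller FDR relative to the rest of
the class, i.e. stronger evidence of driver activity.  Entity classes
are never mixed: genes are standardized against genes, pathways
against pathways.
"""

from __future__ import annotations

import warnings
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = ["driverness_scores", "FDR_FLOOR"]

#: Floor applied to FDR = 0 inputs before the log transform.
FDR_FLOOR = 1e-300


def driverness_scores(
    fdrs: Mapping[str, float],
    sigma_convention: str = "population",
    fdr_floor: float = FDR_FLOOR,
) -> pd.DataFrame:
    """Score a class of entities by Gaussian-standardized -log2(FDR).

    Parameters
    ----------
    fdrs:
        Mapping entity id -> FDR in (0, 1].  FDR = 1 is a valid
        minimum (x = 0); FDR = 0 is floored to ``fdr_floor`` with a
        warning.  At least two entities are required.
    sigma_convention:
        ``"population"`` (divide by n, the default) or ``"sample"``
        (n - 1) for the standard deviation of x.

    Returns
    -------
    DataFrame with columns ``entity``, ``fdr``, ``x``, ``z``,
    ``score``, in the input's iteration order.  If all FDRs are equal
    (sigma = 0) every score is 0.5 and a warning is issued.
    """
    if sigma_convention not in ("population", "sample"):
        raise ValueError(f"unknown sigma convention {sigma_convention!r}")
    entities = list(fdrs)
    if len(entities) < 2:
        raise ValueError("need at least two entities to standardize scores")
    values = np.array([fdrs[e] for e in entities], dtype=float)
    if np.any(values > 1.0) or np.any(values < 0.0) or not np.all(np.isfinite(values)):
        raise ValueError("FDRs must lie in [0, 1]")
    if np.any(values == 0.0):
        warnings.warn(f"FDR = 0 floored to {fdr_floor}", stacklevel=2)
        values = np.maximum(values, fdr_floor)

    x = -np.log2(values)
    mu = float(np.mean(x))
    ddof = 0 if sigma_convention == "population" else 1
    sigma = float(np.std(x, ddof=ddof))
    if sigma == 0.0:
        warnings.warn("all FDRs identical (sigma = 0); every score is 0.5",
                      stacklevel=2)
        z = np.zeros_like(x)
    else:
        z = (x - mu) / sigma
    return pd.DataFrame(
        {"entity": entities, "fdr": values, "x": x, "z": z,
         "score": norm.cdf(z)}
    )
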