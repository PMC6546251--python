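"""Response surfaces reducing the stochastic microtubule grid to formulas.

The population model never calls the stochastic simulator directly.
Instead, a pre-simulation over a (tubulin, hydrolysis-rate) grid is
reduced to two smooth maps:

* ``mean_length(Tu, h)`` — average dynamic-microtubule length, um
* ``degradation_rate(Tu, h)`` — complete-breakdown rate, 1/min

Both are tensor-product cubic polynomials (degree 3 per variable, 16
coefficients) fitted by least squares on the grid means.  Mean length is
cap-limited and therefore nearly exponential in (Tu, h) — it spans two
orders of magnitude over the grid — so its cubic is fitted to the log of
the data by default (``mean_length_space="linear"`` fits the raw values
instead); the degradation surface is fitted in linear space with bounded
relative weights.  Per-point relative residuals are stored so the fit
quality is auditable.  Evaluation outside the fitted rectangle raises,
never extrapolates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.polynomial import polynomial as P

from .errors import DomainError

_DEGREE = (3, 3)


def _normalise(x, lo, hi):
    return (2.0 * (np.asarray(x, dtype=float) - lo) / (hi - lo)) - 1.0


@dataclass(frozen=True)
class ResponseSurfaces:
    """Fitted mean-length and degradation-rate maps over a (Tu, h) rectangle.

    ``coef_mean`` and ``coef_deg`` are 4x4 coefficient matrices in the
    variables normalised to [-1, 1] over ``tu_domain`` x ``h_domain``.
    """

    coef_mean: np.ndarray
    coef_deg: np.ndarray
    tu_domain: tuple
    h_domain: tuple
    fit_residuals: pd.DataFrame
    mean_length_space: str = "log"  # "log": coef_mean fits log(length)

    def _check_domain(self, tu, h):
        tu, h = np.broadcast_arrays(
            np.asarray(tu, dtype=float), np.asarray(h, dtype=float)
        )
        eps = 1e-9
        if np.any(tu < self.tu_domain[0] - eps) or np.any(tu > self.tu_domain[1] + eps):
            raise DomainError(
                f"tubulin_conc {tu} outside fit domain {self.tu_domain}; no extrapolation"
            )
        if np.any(h < self.h_domain[0] - eps) or np.any(h > self.h_domain[1] + eps):
            raise DomainError(
                f"hydrolysis_rate {h} outside fit domain {self.h_domain}; no extrapolation"
            )
        return tu, h

    def mean_length(self, tu, h):
        """Average dynamic-MT length L̄(Tu, h), um."""
        tu, h = self._check_domain(tu, h)
        x = _normalise(tu, *self.tu_domain)
        y = _normalise(h, *self.h_domain)
        val = P.polyval2d(x, y, self.coef_mean)
        return np.exp(val) if self.mean_length_space == "log" else val

    def degradation_rate(self, tu, h):
        """Complete-breakdown rate k_deg(Tu, h), 1/min (clipped at 0)."""
        tu, h = self._check_domain(tu, h)
        x = _normalise(tu, *self.tu_domain)
        y = _normalise(h, *self.h_domain)
        return np.maximum(P.polyval2d(x, y, self.coef_deg), 0.0)

    # -- serialisation -------------------------------------------------

    def to_json(self, path) -> None:
        payload = {
            "tu_domain": list(self.tu_domain),
            "h_domain": list(self.h_domain),
            "coef_mean": self.coef_mean.tolist(),
            "coef_deg": self.coef_deg.tolist(),
            "mean_length_space": self.mean_length_space,
            "fit_residuals": self.fit_residuals.to_dict(orient="list"),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "ResponseSurfaces":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            coef_mean=np.asarray(payload["coef_mean"], dtype=float),
            coef_deg=np.asarray(payload["coef_deg"], dtype=float),
            tu_domain=tuple(payload["tu_domain"]),
            h_domain=tuple(payload["h_domain"]),
            fit_residuals=pd.DataFrame(payload["fit_residuals"]),
            mean_length_space=payload.get("mean_length_space", "log"),
        )


def _fit_one(x, y, z, weights):
    vand = P.polyvander2d(x, y, _DEGREE)
    w = np.sqrt(weights)
    coef, _, rank, _ = np.linalg.lstsq(vand * w[:, None], z * w, rcond=None)
    if rank < vand.shape[1]:
        raise DomainError(
            f"rank-deficient design (rank {rank} < {vand.shape[1]}): "
            "the grid needs at least 4 distinct values per axis"
        )
    return coef.reshape(_DEGREE[0] + 1, _DEGREE[1] + 1)


def fit_surfaces(
    grid_results: pd.DataFrame, mean_length_space: str = "log"
) -> ResponseSurfaces:
    """Fit the two response surfaces to grid summaries.

    ``grid_results`` needs columns ``tubulin_conc, hydrolysis_rate,
    mean_length_um, degradation_rate_per_min`` (replicates are averaged
    per grid point before fitting).  ``mean_length_space="log"`` fits the
    mean-length cubic to log lengths (multiplicative errors, guaranteed
    positivity); ``"linear"`` fits the raw values.
    """
    if mean_length_space not in ("log", "linear"):
        raise DomainError("mean_length_space must be 'log' or 'linear'")
    required = {
        "tubulin_conc",
        "hydrolysis_rate",
        "mean_length_um",
        "degradation_rate_per_min",
    }
    missing = required - set(grid_results.columns)
    if missing:
        raise DomainError(f"grid_results missing columns: {sorted(missing)}")
    agg = (
        grid_results.groupby(["tubulin_conc", "hydrolysis_rate"], as_index=False)[
            ["mean_length_um", "degradation_rate_per_min"]
        ].mean()
    )
    tu_dom = (float(agg.tubulin_conc.min()), float(agg.tubulin_conc.max()))
    h_dom = (float(agg.hydrolysis_rate.min()), float(agg.hydrolysis_rate.max()))
    if agg.tubulin_conc.nunique() < 4 or agg.hydrolysis_rate.nunique() < 4:
        raise DomainError("grid must cover >= 4 distinct points per axis")

    x = _normalise(agg.tubulin_conc.to_numpy(), *tu_dom)
    y = _normalise(agg.hydrolysis_rate.to_numpy(), *h_dom)

    z_mean = agg.mean_length_um.to_numpy()
    z_deg = agg.degradation_rate_per_min.to_numpy()
    if mean_length_space == "log":
        if np.any(z_mean <= 0):
            raise DomainError("mean lengths must be > 0 for the log-space fit")
        coef_mean = _fit_one(x, y, np.log(z_mean), np.ones_like(z_mean))
        fit_mean = np.exp(P.polyval2d(x, y, coef_mean))
    else:
        # bounded relative weighting protects the short-length corner
        w_mean = 1.0 / (z_mean + 0.05 * z_mean.max())
        coef_mean = _fit_one(x, y, z_mean, w_mean)
        fit_mean = P.polyval2d(x, y, coef_mean)
    w_deg = 1.0 / (z_deg + 0.05 * z_deg.max())
    coef_deg = _fit_one(x, y, z_deg, w_deg)
    fit_deg = np.maximum(P.polyval2d(x, y, coef_deg), 0.0)
    residuals = pd.DataFrame(
        {
            "tubulin_conc": agg.tubulin_conc,
            "hydrolysis_rate": agg.hydrolysis_rate,
            "rel_err_mean_length": (fit_mean - z_mean) / np.maximum(z_mean, 1e-12),
            "rel_err_degradation": (fit_deg - z_deg)
            / np.maximum(z_deg, 0.05 * z_deg.max()),
        }
    )
    return ResponseSurfaces(
        coef_mean=coef_mean,
        coef_deg=coef_deg,
        tu_domain=tu_dom,
        h_domain=h_dom,
        fit_residuals=residuals,
        mean_length_space=mean_length_space,
    )
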