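"""Saturation-binding analysis: nonspecific subtraction and one-site Kd fits.

The assay design mirrors a radioligand saturation experiment on
receptor-expressing cells: total-binding wells across a concentration ladder
(here 0.5–64 nM in triplicate) and paired nonspecific wells in which the
receptor is blocked with a large excess of unlabeled peptide.  Specific
binding is the paired difference of means, and the one-site model

    B(c) = Bmax · c / (Kd + c)

is fitted by nonlinear least squares, with standard errors from the
Jacobian-based covariance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .errors import (
    AlignmentError,
    FitFailureError,
    InsufficientDataError,
    InvalidParameterError,
)

__all__ = ["BindingPlate", "KdFitResult", "specific_binding", "fit_one_site", "one_site"]


@dataclass
class BindingPlate:
    """Replicate total and cold-blocked (nonspecific) counts per concentration.

    ``total_counts`` and ``nonspecific_counts`` are (n_concentrations,
    n_replicates) arrays aligned with ``concentrations_nm``.
    """

    concentrations_nm: np.ndarray
    total_counts: np.ndarray
    nonspecific_counts: np.ndarray
    cells_per_well: int = 35000

    def __post_init__(self) -> None:
        self.concentrations_nm = np.asarray(self.concentrations_nm, dtype=float)
        self.total_counts = np.atleast_2d(np.asarray(self.total_counts, dtype=float))
        self.nonspecific_counts = np.atleast_2d(np.asarray(self.nonspecific_counts, dtype=float))
        if np.any(self.concentrations_nm <= 0):
            raise InvalidParameterError("concentrations must be positive")
        n = len(self.concentrations_nm)
        if self.total_counts.shape[0] != n or self.nonspecific_counts.shape[0] != n:
            raise AlignmentError("count arrays must have one row per concentration")

    @classmethod
    def from_csv(cls, path, cells_per_well: int = 35000) -> "BindingPlate":
        """Long-format CSV: concentration_nM, replicate, well_type, counts."""
        df = pd.read_csv(path, comment="#")
        total = df[df["well_type"] == "total"].pivot(
            index="concentration_nM", columns="replicate", values="counts"
        )
        ns = df[df["well_type"] == "nonspecific"].pivot(
            index="concentration_nM", columns="replicate", values="counts"
        )
        if not total.index.equals(ns.index):
            raise AlignmentError("total and nonspecific wells use different concentrations")
        return cls(
            concentrations_nm=total.index.to_numpy(dtype=float),
            total_counts=total.to_numpy(),
            nonspecific_counts=ns.to_numpy(),
            cells_per_well=cells_per_well,
        )

    def to_csv(self, path) -> None:
        rows = []
        for i, c in enumerate(self.concentrations_nm):
            for j, v in enumerate(self.total_counts[i]):
                rows.append((c, j + 1, "total", v))
            for j, v in enumerate(self.nonspecific_counts[i]):
                rows.append((c, j + 1, "nonspecific", v))
        pd.DataFrame(rows, columns=["concentration_nM", "replicate", "well_type", "counts"]).to_csv(
            path, index=False
        )


@dataclass(frozen=True)
class KdFitResult:
    kd_nm: float
    bmax: float
    se_kd_nm: float
    se_bmax: float
    residual_sd: float
    n_points: int
    converged: bool
    n_restarts: int = 0

    def kd_confidence_interval(self, z: float = 1.96) -> tuple[float, float]:
        return (self.kd_nm - z * self.se_kd_nm, self.kd_nm + z * self.se_kd_nm)


def specific_binding(plate: BindingPlate) -> pd.DataFrame:
    """Per-concentration specific binding: mean(total) − mean(nonspecific).

    Negative values are retained (flagged, not clipped) — they are legitimate
    noise outcomes near zero specific signal.
    """
    total_mean = plate.total_counts.mean(axis=1)
    ns_mean = plate.nonspecific_counts.mean(axis=1)
    spec = total_mean - ns_mean
    return pd.DataFrame(
        {
            "concentration_nM": plate.concentrations_nm,
            "total_mean": total_mean,
            "total_sd": plate.total_counts.std(axis=1, ddof=1)
            if plate.total_counts.shape[1] > 1 else np.nan,
            "nonspecific_mean": ns_mean,
            "specific": spec,
            "negative": spec < 0,
        }
    )


def one_site(c, bmax, kd):
    """One-site saturation model B(c) = Bmax·c/(Kd + c)."""
    return bmax * c / (kd + c)


def fit_one_site(
    concentrations_nm: np.ndarray,
    specific: np.ndarray,
    max_restarts: int = 5,
) -> KdFitResult:
    """Least-squares one-site fit of specific binding vs concentration.

    Initialisation: Bmax₀ = max observed specific binding, Kd₀ = the
    concentration whose response is nearest Bmax₀/2; both bounded positive.
    On non-convergence the starting point is jittered up to ``max_restarts``
    times before a fit-failure error is raised.
    """
    c = np.asarray(concentrations_nm, dtype=float)
    y = np.asarray(specific, dtype=float)
    if len(np.unique(c)) < 4:
        raise InsufficientDataError("need >= 4 distinct concentrations for a one-site fit")
    bmax0 = max(float(y.max()), 1e-9)
    kd0 = float(c[np.argmin(np.abs(y - bmax0 / 2.0))])
    last_error: Exception | None = None
    rng = np.random.default_rng(0)  # deterministic jitter for restarts
    for attempt in range(max_restarts + 1):
        scale = 1.0 if attempt == 0 else float(rng.lognormal(0.0, 0.5))
        try:
            popt, pcov = optimize.curve_fit(
                one_site, c, y,
                p0=[bmax0 * scale, kd0 * scale],
                bounds=([1e-12, 1e-12], [np.inf, np.inf]),
                maxfev=20000,
            )
        except (RuntimeError, ValueError) as err:
            last_error = err
            continue
        bmax, kd = popt
        resid = y - one_site(c, *popt)
        dof = max(len(c) - 2, 1)
        residual_sd = float(np.sqrt(np.sum(resid**2) / dof))
        se = np.sqrt(np.diag(pcov))
        return KdFitResult(
            kd_nm=float(kd), bmax=float(bmax),
            se_kd_nm=float(se[1]), se_bmax=float(se[0]),
            residual_sd=residual_sd, n_points=len(c),
            converged=True, n_restarts=attempt,
        )
    raise FitFailureError(f"one-site fit failed after {max_restarts} restarts: {last_error}")
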