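"""Free-energy reweighting of boosted (Gaussian-accelerated) sampling.

A GaMD run samples configurations under ``U + ΔV`` with a non-negative
boost ``ΔV``.  The canonical potential of mean force over binned collective
variables is recovered with a Maclaurin/cumulant expansion of the
exponential reweighting factor: to second order, each bin j contributes

    F(j) = -kT [ ln p*(j) + β·mean(ΔV)_j + β²·var(ΔV)_j / 2 ] + C,

where ``p*`` is the boosted histogram fraction and C shifts the minimum of
the unmasked bins to zero.  The second-order form is exact when ΔV is
Gaussian within a bin, which is the working regime of Gaussian-accelerated
sampling; the first-order form is kept as a diagnostic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .errors import CoverageError

__all__ = ["KB", "BoostSeries", "PMFGrid", "boost_statistics", "reweight_pmf",
           "read_boost_series"]

#: Boltzmann constant, kcal/(mol K).
KB = 0.0019872041


@dataclass
class BoostSeries:
    """Per-frame boost potential ΔV (kcal/mol) at a simulation temperature."""

    delta_v: np.ndarray
    temperature: float = 300.0  # K

    def __post_init__(self) -> None:
        self.delta_v = np.asarray(self.delta_v, dtype=float)
        if self.delta_v.ndim != 1:
            raise ValueError("delta_v must be one-dimensional")
        if not np.all(np.isfinite(self.delta_v)):
            raise ValueError("delta_v contains non-finite values")
        if np.any(self.delta_v < -1e-9):
            raise ValueError("boost potential must be non-negative")

    @property
    def beta(self) -> float:
        return 1.0 / (KB * self.temperature)

    def __len__(self) -> int:
        return self.delta_v.size


@dataclass
class PMFGrid:
    """Binned free-energy surface over 1 or 2 collective variables."""

    edges: list[np.ndarray]
    free_energy: np.ndarray  # kcal/mol, min over unmasked bins == 0
    counts: np.ndarray
    masked: np.ndarray  # True where count < min_samples
    order: int = 2
    temperature: float = 300.0

    @property
    def centers(self) -> list[np.ndarray]:
        return [0.5 * (e[1:] + e[:-1]) for e in self.edges]

    def to_dict(self) -> dict:
        return {
            "edges": [e.tolist() for e in self.edges],
            "free_energy": np.where(self.masked, np.nan, self.free_energy).tolist(),
            "counts": self.counts.tolist(),
            "masked": self.masked.tolist(),
            "order": self.order,
            "temperature": self.temperature,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PMFGrid":
        masked = np.asarray(d["masked"], bool)
        fe = np.asarray(d["free_energy"], float)
        fe = np.where(masked, np.inf, np.nan_to_num(fe, nan=np.inf))
        return cls(
            edges=[np.asarray(e, float) for e in d["edges"]],
            free_energy=fe,
            counts=np.asarray(d["counts"], int),
            masked=masked,
            order=int(d["order"]),
            temperature=float(d["temperature"]),
        )


def boost_statistics(b: BoostSeries) -> tuple[float, float, float]:
    """(mean, population std, skewness) of the boost series.

    The skewness is the Gaussianity diagnostic: cumulant reweighting is
    trustworthy when it is near zero.  A constant series reports 0 skew.
    """
    if len(b) < 2:
        raise ValueError("need at least 2 boost samples")
    mean = float(b.delta_v.mean())
    std = float(b.delta_v.std(ddof=0))
    skew = float(sps.skew(b.delta_v, bias=True)) if std > 0 else 0.0
    return mean, std, skew


def reweight_pmf(
    cv: np.ndarray,
    boost: BoostSeries,
    bins: int | list = 50,
    order: int = 2,
    min_samples: int = 10,
) -> PMFGrid:
    """Cumulant-expansion reweighted PMF on a 1D or 2D grid.

    With ΔV identically zero this reduces exactly to the unweighted
    histogram estimate −kT ln(count/max count); adding a constant to ΔV
    changes nothing (absorbed in the normalization shift).  Bins holding
    fewer than ``min_samples`` frames are masked, not extrapolated.
    """
    if order not in (1, 2):
        raise ValueError(f"cumulant order must be 1 or 2, got {order}")
    cv = np.asarray(cv, dtype=float)
    if cv.ndim == 1:
        cv = cv[:, None]
    if cv.ndim != 2 or cv.shape[1] not in (1, 2):
        raise ValueError("cv must have 1 or 2 columns")
    if cv.shape[0] != len(boost):
        raise ValueError("cv and boost series lengths differ")

    counts, edges = np.histogramdd(cv, bins=bins)
    counts = counts.astype(int)
    # flat bin index per frame
    flat = np.zeros(cv.shape[0], dtype=int)
    shape = counts.shape
    for d in range(cv.shape[1]):
        e = edges[d]
        k = np.clip(np.searchsorted(e, cv[:, d], side="right") - 1, 0, shape[d] - 1)
        flat = flat * shape[d] + k

    nbins = counts.size
    sum_dv = np.bincount(flat, weights=boost.delta_v, minlength=nbins)
    sum_dv2 = np.bincount(flat, weights=boost.delta_v**2, minlength=nbins)
    cflat = counts.reshape(-1).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        mean_dv = np.where(cflat > 0, sum_dv / cflat, 0.0)
        var_dv = np.where(cflat > 0, sum_dv2 / cflat - mean_dv**2, 0.0)
        var_dv = np.maximum(var_dv, 0.0)
        logp = np.where(cflat > 0, np.log(cflat / cv.shape[0]), -np.inf)

    beta = boost.beta
    kt = 1.0 / beta
    f = -kt * logp - mean_dv
    if order == 2:
        f = f - beta * var_dv / 2.0

    masked = cflat < max(min_samples, 1)
    if masked.all():
        raise CoverageError("all bins are under-sampled; nothing to report")
    f = f - f[~masked].min()
    f = np.where(masked, np.inf, f)
    return PMFGrid(
        edges=[np.asarray(e) for e in edges],
        free_energy=f.reshape(shape),
        counts=counts,
        masked=masked.reshape(shape),
        order=order,
        temperature=boost.temperature,
    )


def read_boost_series(path, temperature: float = 300.0, column: int = 1) -> BoostSeries:
    """Read ΔV from plain-text columns (default: second column, kcal/mol).

    Accepts the simple two-column ``frame ΔV`` layout; for AMBER-style
    gamd.log subsets pass the appropriate 0-based ``column``.
    """
    data = np.loadtxt(path, comments=("#", "|"))
    if data.ndim == 1:
        data = data[:, None]
        column = 0
    return BoostSeries(delta_v=data[:, column], temperature=temperature)
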