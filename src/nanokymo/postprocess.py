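"""Probability-sum thresholding and single-pass 3-sigma outlier pruning.

A kymograph is kept only if the total probability mass of its presence
map reaches half the average mass observed in buffer-only control
recordings; the surviving molecular-weight and hydrodynamic-radius
estimates are then pruned by a single Gaussian moment fit (sample mean
and n-1 standard deviation) with a strict |v - mu| > 3 sigma cut.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .hvit import MoleculeEstimate, ProbabilityMap

__all__ = [
    "PopulationSummary",
    "probability_total",
    "compute_threshold",
    "apply_threshold",
    "prune_outliers",
    "summarize",
]


@dataclass(frozen=True)
class PopulationSummary:
    n_accepted: int
    mw_mean: float
    mw_median: float
    mw_std: float
    rs_mean: float
    rs_median: float
    rs_std: float
    threshold_used: float

    def __post_init__(self):
        if self.n_accepted < 0:
            raise ValueError("n_accepted must be non-negative")


def probability_total(p: ProbabilityMap | np.ndarray) -> float:
    """Total probability mass: the plain sum over all map bins."""
    values = p.values if isinstance(p, ProbabilityMap) else np.asarray(p)
    return float(values.sum())


def compute_threshold(control_totals: Sequence[float]) -> float:
    """Half the arithmetic mean of the control probability totals."""
    totals = np.asarray(control_totals, dtype=np.float64)
    if totals.size == 0:
        raise ValueError("need at least one control total")
    return 0.5 * float(totals.mean())


def apply_threshold(estimates: Sequence[MoleculeEstimate],
                    thresh: float) -> list[MoleculeEstimate]:
    """Keep estimates with p_total >= thresh; flags are set on every input."""
    if thresh < 0:
        raise ValueError("threshold must be non-negative")
    out = []
    for e in estimates:
        accepted = e.p_total >= thresh
        out.append(replace(e, accepted=accepted))
    return [e for e in out if e.accepted]


def prune_outliers(values: Sequence[float]) -> tuple[np.ndarray, float, float]:
    """Single-pass Gaussian moment fit and strict 3-sigma cut.

    Returns (kept values, fitted mean, fitted std).  Points exactly at
    mu +/- 3 sigma are kept; the fit is not repeated after removal.
    """
    v = np.asarray(values, dtype=np.float64)
    if v.size < 2:
        raise ValueError("need at least 2 values to fit")
    mu = float(v.mean())
    sigma = float(v.std(ddof=1))
    kept = v[np.abs(v - mu) <= 3.0 * sigma]
    return kept, mu, sigma


def summarize(estimates: Sequence[MoleculeEstimate],
              threshold_used: float = 0.0) -> PopulationSummary:
    """Population statistics over accepted estimates after joint pruning.

    MW and Rs are pruned independently; a kymograph flagged as an outlier
    in either dimension is excluded from both summaries.
    """
    accepted = [e for e in estimates if e.accepted]
    if not accepted:
        raise ValueError("no accepted estimates to summarize")
    mw = np.array([e.mw_kDa for e in accepted])
    rs = np.array([e.rs_nm for e in accepted])
    if mw.size >= 2:
        _, mw_mu, mw_sd = prune_outliers(mw)
        _, rs_mu, rs_sd = prune_outliers(rs)
        keep = (np.abs(mw - mw_mu) <= 3.0 * mw_sd) & (np.abs(rs - rs_mu) <= 3.0 * rs_sd)
        mw, rs = mw[keep], rs[keep]
    return PopulationSummary(
        n_accepted=int(mw.size),
        mw_mean=float(mw.mean()),
        mw_median=float(np.median(mw)),
        mw_std=float(mw.std(ddof=1)) if mw.size > 1 else 0.0,
        rs_mean=float(rs.mean()),
        rs_median=float(np.median(rs)),
        rs_std=float(rs.std(ddof=1)) if rs.size > 1 else 0.0,
        threshold_used=threshold_used,
    )
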