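"""Volume-density relationship per dataset class.

All analyses operate in natural-log space: Pearson correlation between
ln V and ln d, and ordinary least squares of ln d on ln V (a power-law
fit d = c * V**gamma).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .objects_io import ObjectTable, concat_tables


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson correlation with exact t-transform p-value."""

    r: float
    n: int
    p: float
    variables: str = "ln V vs ln d"

    @property
    def significant(self) -> bool:
        return self.p < 0.05


@dataclass(frozen=True)
class PowerLawFit:
    """d = c * V**gamma fitted by OLS in log-log space."""

    c: float
    gamma: float
    residual_sd: float
    n: int

    def predict_density(self, volume: float) -> float:
        return self.c * volume ** self.gamma


def _log_arrays(table: ObjectTable) -> tuple[np.ndarray, np.ndarray]:
    v = np.array([r.volume for r in table])
    d = np.array([r.density for r in table])
    return np.log(v), np.log(d)


def log_log_correlation(table: ObjectTable) -> CorrelationResult:
    """Pearson r between ln(volume) and ln(density).

    The two-sided p-value uses the exact transform
    t = r * sqrt((n-2) / (1-r^2)) with n-2 degrees of freedom.

    Raises
    ------
    ValueError
        For fewer than 3 records or zero variance in either variable.
    """
    if len(table) < 3:
        raise ValueError(f"need at least 3 records, got {len(table)}")
    lv, ld = _log_arrays(table)
    if np.ptp(lv) == 0 or np.ptp(ld) == 0:
        raise ValueError("zero variance in log volume or log density")
    n = len(lv)
    r = float(np.corrcoef(lv, ld)[0, 1])
    if abs(r) >= 1.0:
        p = 0.0
    else:
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
        p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    return CorrelationResult(r=r, n=n, p=p)


def fit_power_law(table: ObjectTable) -> PowerLawFit:
    """OLS of ln d on ln V: gamma = slope, c = exp(intercept).

    ``residual_sd`` is the root mean squared residual in log space.
    """
    if len(table) < 3:
        raise ValueError(f"need at least 3 records, got {len(table)}")
    lv, ld = _log_arrays(table)
    if np.ptp(lv) == 0:
        raise ValueError("zero variance in log volume")
    slope, intercept = np.polyfit(lv, ld, 1)
    resid = ld - (slope * lv + intercept)
    return PowerLawFit(
        c=float(np.exp(intercept)),
        gamma=float(slope),
        residual_sd=float(np.sqrt(np.mean(resid**2))),
        n=len(lv),
    )


def random_subset(table: ObjectTable, n: int, seed: int) -> ObjectTable:
    """Seeded random n-record subset (order preserved)."""
    if n > len(table):
        raise ValueError(f"cannot take {n} of {len(table)} records")
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(len(table), size=n, replace=False))
    return ObjectTable(
        [table.records[i] for i in idx],
        provenance=f"{table.provenance} (random n={n}, seed={seed})",
    )


def dataset_contrast(tables: dict[str, ObjectTable]) -> dict[str, CorrelationResult]:
    """Per-table log-log correlations plus a pooled liftable-artificial one.

    The pooled entry (key ``"pooled_artificial_liftable"``) combines every
    table whose records are all artificial and liftable.
    """
    results: dict[str, CorrelationResult] = {}
    pooled_candidates = []
    for name, table in tables.items():
        if len(table) == 0:
            raise ValueError(f"table {name!r} is empty")
        results[name] = log_log_correlation(table)
        if all(r.category == "artificial" and r.liftable for r in table):
            pooled_candidates.append(table)
    if len(pooled_candidates) > 1:
        pooled = concat_tables(pooled_candidates, provenance="pooled artificial liftable")
        results["pooled_artificial_liftable"] = log_log_correlation(pooled)
    return results
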