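"""Small/large object-pair ratios and the ratio-line machinery.

For each ordered pair with V_small < V_large we store natural-log ratios:

    VR = ln(V_S / V_L) < 0
    WR = ln(w_S / w_L)
    DR = ln(d_S / d_L) = WR - VR   (exact identity, since d = w/V)

Lines are OLS fits of WR (or DR) on VR over a pair set; because of the
identity, the density line's slope is always the weight line's slope
minus one, with identical intercepts.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .objects_io import ObjectTable

#: canonical pair labels for a four-object stimulus set, in table order
STIMULUS_PAIRS = ("AB", "AC", "AD", "BC", "BD", "CD")

#: measured volumes (cm^3) of the three four-object stimulus families,
#: each built with nominal volume proportions 1 : 3.375 : 8 : 27
STIMULUS_VOLUMES: dict[str, tuple[float, float, float, float]] = {
    "Blobs": (111.63, 376.75, 893.03, 3013.98),
    "Greebles": (65.72, 221.80, 525.75, 1774.41),
    "Cubes": (131.10, 442.45, 1048.77, 3539.61),
}


def stimulus_volume_ratios(
    volumes: dict[str, tuple[float, float, float, float]] | None = None,
) -> dict[str, dict[str, float]]:
    """Per-family small/large volume ratios, {family: {pair: ratio}}."""
    volumes = STIMULUS_VOLUMES if volumes is None else volumes
    return {name: stimulus_pair_table(v) for name, v in volumes.items()}


@dataclass(frozen=True)
class PairRatio:
    """One small/large object pair with natural-log ratios."""

    small_id: str
    large_id: str
    VR: float
    WR: float

    def __post_init__(self) -> None:
        if not self.VR < 0:
            raise ValueError(f"VR must be strictly negative, got {self.VR}")

    @property
    def DR(self) -> float:
        """ln density ratio; identically WR - VR."""
        return self.WR - self.VR

    @property
    def volume_ratio(self) -> float:
        return math.exp(self.VR)

    @property
    def weight_ratio(self) -> float:
        return math.exp(self.WR)

    @property
    def density_ratio(self) -> float:
        return math.exp(self.DR)


@dataclass(frozen=True)
class RatioLine:
    """Slope/intercept of a log-ratio line over log volume ratio."""

    slope: float
    intercept: float
    kind: str  # "weight" or "density"
    n_pairs: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("weight", "density"):
            raise ValueError(f"kind must be 'weight' or 'density', got {self.kind!r}")

    def to_density_line(self) -> "RatioLine":
        """Density line implied by this weight line (slope - 1, same intercept)."""
        if self.kind == "density":
            return self
        return RatioLine(self.slope - 1.0, self.intercept, "density", self.n_pairs)

    def to_weight_line(self) -> "RatioLine":
        if self.kind == "weight":
            return self
        return RatioLine(self.slope + 1.0, self.intercept, "weight", self.n_pairs)


def build_pairs(table: ObjectTable) -> list[PairRatio]:
    """All n(n-1)/2 pairs oriented small -> large.

    Pairs with exactly equal volumes have no small/large orientation and
    are dropped.

    Raises
    ------
    ValueError
        For fewer than 2 records.
    """
    if len(table) < 2:
        raise ValueError(f"need at least 2 records, got {len(table)}")
    pairs = []
    for a, b in itertools.combinations(table.records, 2):
        if a.volume == b.volume:
            continue
        small, large = (a, b) if a.volume < b.volume else (b, a)
        pairs.append(
            PairRatio(
                small_id=small.id,
                large_id=large.id,
                VR=math.log(small.volume / large.volume),
                WR=math.log(small.weight / large.weight),
            )
        )
    return pairs


def fit_ratio_line(pairs: list[PairRatio], kind: str) -> RatioLine:
    """OLS of WR (kind='weight') or DR (kind='density') on VR."""
    if kind not in ("weight", "density"):
        raise ValueError(f"kind must be 'weight' or 'density', got {kind!r}")
    if len(pairs) < 2:
        raise ValueError(f"need at least 2 pairs, got {len(pairs)}")
    vr = np.array([p.VR for p in pairs])
    if np.ptp(vr) == 0:
        raise ValueError("degenerate design: constant VR across pairs")
    y = np.array([p.WR if kind == "weight" else p.DR for p in pairs])
    slope, intercept = np.polyfit(vr, y, 1)
    return RatioLine(float(slope), float(intercept), kind, n_pairs=len(pairs))


def predict_ratio(line: RatioLine, volume_ratio: float) -> float:
    """Predicted small/large ratio at a small/large volume ratio in (0, 1].

    Returns exp(slope * ln(volume_ratio) + intercept).
    """
    if not 0.0 < volume_ratio <= 1.0:
        raise ValueError(f"volume_ratio must be in (0, 1], got {volume_ratio}")
    return math.exp(line.slope * math.log(volume_ratio) + line.intercept)


def density_ratio_from_weight(weight_ratio: float, volume_ratio: float) -> float:
    """d_S/d_L from w_S/w_L and V_S/V_L: weight_ratio / volume_ratio."""
    if weight_ratio <= 0 or volume_ratio <= 0:
        raise ValueError("ratios must be strictly positive")
    return weight_ratio / volume_ratio


def stimulus_pair_table(volumes: tuple[float, float, float, float]) -> dict[str, float]:
    """Six small/large volume ratios for a four-object stimulus set.

    ``volumes`` must be strictly increasing (objects A < B < C < D).
    Returns {pair label: V_small / V_large}.
    """
    if len(volumes) != 4:
        raise ValueError(f"need exactly 4 volumes, got {len(volumes)}")
    a, b, c, d = volumes
    if not (a < b < c < d):
        raise ValueError(f"volumes must be strictly increasing, got {volumes}")
    return {
        "AB": a / b,
        "AC": a / c,
        "AD": a / d,
        "BC": b / c,
        "BD": b / d,
        "CD": c / d,
    }


def prediction_table(weight_line: RatioLine,
                     volume_ratios: dict[str, float]) -> pd.DataFrame:
    """Predicted environmental weight and density ratios per pair.

    Density predictions apply the ratio identity d_S/d_L =
    (w_S/w_L) * (V_L/V_S) to the predicted weight ratios.
    """
    rows = []
    for pair, vratio in volume_ratios.items():
        w = predict_ratio(weight_line, vratio)
        rows.append(
            {
                "pair": pair,
                "volume_ratio": vratio,
                "predicted_weight_ratio": w,
                "predicted_density_ratio": density_ratio_from_weight(w, vratio),
            }
        )
    return pd.DataFrame(rows)


def pairs_to_frame(pairs: list[PairRatio]) -> pd.DataFrame:
    """Pairs CSV layout: small_id, large_id, VR, WR, DR."""
    return pd.DataFrame(
        [
            {"small_id": p.small_id, "large_id": p.large_id,
             "VR": p.VR, "WR": p.WR, "DR": p.DR}
            for p in pairs
        ],
        columns=["small_id", "large_id", "VR", "WR", "DR"],
    )
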