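"""Reach-level habitat indices aggregated from per-cell suitability.

Given per-cell areas A_i (m2) and suitability indices HSI_i in [0, 1]:

* WUA  = sum A_i * HSI_i              weighted usable area (m2)
* OSI  = WUA / sum A_i                overall suitability index
* ISP  = area fraction with HSI >= 0.7            (%)
* MSP  = area fraction with 0.3 <= HSI < 0.7      (%)
* LSP  = area fraction with HSI < 0.3             (%)

The class bins follow the half-open printed convention (>= 0.7; [0.3, 0.7);
< 0.3), so ISP + MSP + LSP = 100 % exactly before display rounding.
Dry cells (missing or non-positive depth) are excluded from every sum.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "REQUIRED_COLUMNS",
    "MetricThresholds",
    "HabitatSummary",
    "drop_dry",
    "wua",
    "osi",
    "suitability_proportions",
    "summarize",
]

log = logging.getLogger(__name__)

#: Columns a cell field must carry before habitat evaluation.
REQUIRED_COLUMNS = ("cell_id", "area_m2", "depth_m", "velocity_ms")


@dataclass(frozen=True)
class MetricThresholds:
    ideal: float = 0.7
    low: float = 0.3

    def __post_init__(self) -> None:
        if not 0.0 < self.low < self.ideal < 1.0:
            raise ValueError("require 0 < low < ideal < 1")


@dataclass(frozen=True)
class HabitatSummary:
    """One period's reach-level indices (one output-table row)."""

    period: str
    wua_m2: float
    osi: float
    isp_pct: float
    msp_pct: float
    lsp_pct: float

    def as_row(self) -> dict:
        """Display row in the published table layout (rounded)."""
        return {
            "Period": self.period,
            "WUA_m2": self.wua_m2,
            "WUA_1e5_m2": round(self.wua_m2 / 1e5, 2),
            "OSI": round(self.osi, 2),
            "ISP": round(self.isp_pct, 2),
            "MSP": round(self.msp_pct, 2),
            "LSP": round(self.lsp_pct, 2),
        }


def _validated(cells: pd.DataFrame, need_hsi: bool) -> pd.DataFrame:
    if "area_m2" not in cells.columns:
        raise ValueError("cell field lacks an area_m2 column")
    if need_hsi and ("hsi" not in cells.columns or cells["hsi"].isna().any()):
        raise ValueError("cell field lacks per-cell HSI; evaluate the model first")
    if len(cells) == 0:
        raise ValueError("empty cell field")
    if (cells["area_m2"] <= 0).any():
        raise ValueError("cell areas must be positive")
    if need_hsi:
        h = cells["hsi"].to_numpy()
        if ((h < 0) | (h > 1)).any():
            raise ValueError("HSI values must lie in [0, 1]")
    return cells


def drop_dry(cells: pd.DataFrame) -> pd.DataFrame:
    """Remove cells with missing or non-positive depth (dry cells)."""
    if "depth_m" not in cells.columns:
        return cells
    wet = cells["depth_m"].notna() & (cells["depth_m"] > 0)
    n_dry = int((~wet).sum())
    if n_dry:
        log.info("excluding %d dry cell(s) of %d", n_dry, len(cells))
    return cells.loc[wet]


def wua(cells: pd.DataFrame) -> float:
    """Weighted usable area (m2): sum of area * HSI over wetted cells."""
    cells = _validated(cells, need_hsi=True)
    return float((cells["area_m2"] * cells["hsi"]).sum())


def osi(cells: pd.DataFrame) -> float:
    """Overall suitability index: WUA normalized by total wetted area."""
    cells = _validated(cells, need_hsi=True)
    total = float(cells["area_m2"].sum())
    if total <= 0:
        raise ValueError("total cell area is zero")
    return wua(cells) / total


def suitability_proportions(
    cells: pd.DataFrame, thresholds: MetricThresholds = MetricThresholds()
) -> tuple[float, float, float]:
    """(ISP, MSP, LSP) area percentages with half-open class bins."""
    cells = _validated(cells, need_hsi=True)
    a = cells["area_m2"].to_numpy(dtype=float)
    h = cells["hsi"].to_numpy(dtype=float)
    total = a.sum()
    isp = a[h >= thresholds.ideal].sum() / total * 100.0
    msp = a[(h >= thresholds.low) & (h < thresholds.ideal)].sum() / total * 100.0
    lsp = a[h < thresholds.low].sum() / total * 100.0
    return float(isp), float(msp), float(lsp)


def summarize(
    cells: pd.DataFrame,
    thresholds: MetricThresholds = MetricThresholds(),
    period: str = "",
) -> HabitatSummary:
    """Bundle WUA, OSI and the class proportions for one period."""
    isp, msp, lsp = suitability_proportions(cells, thresholds)
    return HabitatSummary(
        period=period,
        wua_m2=wua(cells),
        osi=osi(cells),
        isp_pct=isp,
        msp_pct=msp,
        lsp_pct=lsp,
    )
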