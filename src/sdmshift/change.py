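"""Consensus binarization, dispersal rules, and stacked change maps.

Per-species replicate maps are binarized at their own training-presence
thresholds, combined by strict majority into a consensus presence map, and
(for the no-dispersal assumption) intersected with the current consensus.
Summing consensus maps across species yields richness; differencing
current and future per-species maps yields gain/loss counts, and turnover
is their unnormalized sum SG + SL (species gained plus species lost; under
no dispersal gains are impossible, so turnover equals losses).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigError
from .grid import RasterGrid


def binarize(logistic_map: RasterGrid, threshold: float) -> RasterGrid:
    """Presence where score >= threshold (ties count as presence)."""
    vals = (logistic_map.values >= threshold).astype(float)
    vals[logistic_map.mask] = 0.0
    return logistic_map.like(vals)


def consensus(replicate_binary_maps: list[RasterGrid]) -> RasterGrid:
    """Strict-majority vote: presence iff more than R/2 of R replicate maps
    agree (for R=10 that is at least 6; an exact R/2 split is absence)."""
    if not replicate_binary_maps:
        raise ConfigError("need at least one replicate map")
    first = replicate_binary_maps[0]
    for m in replicate_binary_maps[1:]:
        first.assert_aligned(m)
    counts = np.sum([m.values for m in replicate_binary_maps], axis=0)
    out = (counts > len(replicate_binary_maps) / 2.0).astype(float)
    out[first.mask] = 0.0
    return first.like(out)


def apply_no_dispersal(current: RasterGrid, future: RasterGrid) -> RasterGrid:
    """Pixelwise AND: a future presence requires presence in both maps."""
    current.assert_aligned(future)
    vals = ((current.values > 0) & (future.values > 0)).astype(float)
    vals[current.mask] = 0.0
    return current.like(vals)


def stack_richness(per_species_maps: dict[str, RasterGrid]) -> RasterGrid:
    """Sum binary consensus maps across species into integer richness."""
    if len(per_species_maps) == 0:
        raise ConfigError("no species maps")
    if len(set(per_species_maps)) != len(per_species_maps):  # pragma: no cover
        raise ConfigError("duplicate species")
    maps = list(per_species_maps.values())
    first = maps[0]
    for m in maps[1:]:
        first.assert_aligned(m)
    total = np.sum([m.values for m in maps], axis=0)
    total[first.mask] = 0.0
    return first.like(total)


def gains_losses(current: RasterGrid, future: RasterGrid) -> tuple[RasterGrid, RasterGrid]:
    """Per-species gain (newly occupied) and loss (vacated) binary maps."""
    current.assert_aligned(future)
    cur = current.values > 0
    fut = future.values > 0
    gain = (fut & ~cur).astype(float)
    loss = (cur & ~fut).astype(float)
    gain[current.mask] = 0.0
    loss[current.mask] = 0.0
    return current.like(gain), current.like(loss)


def sum_maps(maps: list[RasterGrid]) -> RasterGrid:
    first = maps[0]
    for m in maps[1:]:
        first.assert_aligned(m)
    total = np.sum([m.values for m in maps], axis=0)
    total[first.mask] = 0.0
    return first.like(total)


def turnover(gain_raster: RasterGrid, loss_raster: RasterGrid) -> RasterGrid:
    """Species turnover SG + SL per cell (unnormalized: dividing by local
    richness blows up where richness is near zero)."""
    gain_raster.assert_aligned(loss_raster)
    vals = gain_raster.values + loss_raster.values
    vals[gain_raster.mask] = 0.0
    return gain_raster.like(vals)


@dataclass
class ChangeSummary:
    """Per-pixel change layers for one scenario x time x dispersal cell."""

    scenario_tag: str
    dispersal: str
    richness_future: RasterGrid
    change: RasterGrid
    gains: RasterGrid
    losses: RasterGrid
    turnover: RasterGrid

    def means(self) -> dict[str, float]:
        return {
            "mean_richness": self.richness_future.mean(),
            "mean_gain": self.gains.mean(),
            "mean_loss": self.losses.mean(),
            "mean_turnover": self.turnover.mean(),
        }


def summarize_change(
    current_maps: dict[str, RasterGrid],
    future_maps: dict[str, RasterGrid],
    scenario_tag: str,
    dispersal: str,
) -> ChangeSummary:
    """Assemble the full change summary for one future map set.

    current_maps / future_maps give the per-species binary consensus maps;
    the identity change = richness(future) - richness(current) =
    gains - losses holds exactly by construction.
    """
    if set(current_maps) != set(future_maps):
        raise ConfigError("current and future map sets cover different species")
    gain_list, loss_list = [], []
    for sid in sorted(current_maps):
        g, l = gains_losses(current_maps[sid], future_maps[sid])
        gain_list.append(g)
        loss_list.append(l)
    gains = sum_maps(gain_list)
    losses = sum_maps(loss_list)
    rich_cur = stack_richness(current_maps)
    rich_fut = stack_richness(future_maps)
    change = rich_fut.like(rich_fut.values - rich_cur.values)
    return ChangeSummary(
        scenario_tag=scenario_tag,
        dispersal=dispersal,
        richness_future=rich_fut,
        change=change,
        gains=gains,
        losses=losses,
        turnover=turnover(gains, losses),
    )
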