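"""Single-walker motility experiments.

A walker is one bacterium placed at a uniform random empty pixel and moved
for a fixed horizon (default 500 steps) with the growth model's movement
rule but *without* death, duplication, or any energy gating of motion.  Two
statistics summarise each run:

``p_outside``
    Fraction of the ``horizon`` observed positions (classified after each
    step; the initial position is not counted) lying outside the pillar
    periphery band.
``D_tot``
    Total count of successful one-pixel moves — motility, not net
    displacement — bounded above by the horizon.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._kernels import run_walker_kernel
from .arrangements import ConfigurationError, PillarLayout, periphery_mask
from .simulator import derive_seeds

__all__ = [
    "MotilityRecord",
    "run_single_walker",
    "motility_ensemble",
    "distribution_mode",
    "motility_correlation",
    "records_to_dataframe",
]


@dataclass(frozen=True)
class MotilityRecord:
    """Outcome of one movement-only walker run."""

    p_outside: float
    d_tot: int
    start_position: tuple[int, int]
    seed: int


def run_single_walker(layout: PillarLayout, horizon: int = 500, seed: int = 0) -> MotilityRecord:
    """One walker for ``horizon`` steps; returns its (p_outside, D_tot) record."""
    if horizon < 1:
        raise ConfigurationError("horizon must be ≥ 1")
    if layout.empty_pixel_count < 1:
        raise ConfigurationError("layout has no empty pixels")
    peri = periphery_mask(layout)
    r0, c0, d_tot, outside = run_walker_kernel(
        layout.obstacle_mask, peri.mask, int(horizon), int(seed)
    )
    return MotilityRecord(outside / horizon, int(d_tot), (int(r0), int(c0)), int(seed))


def motility_ensemble(
    layout: PillarLayout, n_runs: int = 1000, horizon: int = 500, seed: int = 0
) -> list[MotilityRecord]:
    """``n_runs`` independent walkers with sub-seeds derived from ``seed``."""
    if n_runs < 1:
        raise ConfigurationError("n_runs must be ≥ 1")
    peri = periphery_mask(layout)
    records = []
    for s in derive_seeds(seed, n_runs):
        r0, c0, d_tot, outside = run_walker_kernel(
            layout.obstacle_mask, peri.mask, int(horizon), int(s)
        )
        records.append(
            MotilityRecord(outside / horizon, int(d_tot), (int(r0), int(c0)), int(s))
        )
    return records


def distribution_mode(values, bin_width: float = 0.05) -> float:
    """Centre of the fullest histogram bin over [0, 1]; ties break low.

    Quantifies "the distribution peaks around x" for fraction-valued
    statistics such as p_outside.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ConfigurationError("values must be non-empty")
    if not 0 < bin_width <= 1:
        raise ConfigurationError("bin_width must be in (0, 1]")
    n_bins = max(1, round(1 / bin_width))
    counts, edges = np.histogram(values, bins=n_bins, range=(0.0, 1.0))
    i = int(np.argmax(counts))  # first maximum → lower bin on ties
    return float((edges[i] + edges[i + 1]) / 2)


def motility_correlation(records: list[MotilityRecord]) -> float:
    """Pearson correlation between p_outside and D_tot across walkers."""
    if len(records) < 3:
        raise ConfigurationError("need at least 3 records")
    p = np.array([r.p_outside for r in records])
    d = np.array([r.d_tot for r in records], dtype=float)
    if np.ptp(p) == 0 or np.ptp(d) == 0:
        raise ConfigurationError("correlation undefined for constant inputs")
    return float(stats.pearsonr(p, d).statistic)


def records_to_dataframe(records: list[MotilityRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "replicate": np.arange(len(records)),
            "seed": [r.seed for r in records],
            "p_outside": [r.p_outside for r in records],
            "d_tot": [r.d_tot for r in records],
            "start_row": [r.start_position[0] for r in records],
            "start_col": [r.start_position[1] for r in records],
        }
    )
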