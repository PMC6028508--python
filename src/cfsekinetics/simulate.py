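"""Agent-based Monte-Carlo generator of dye-dilution experiments.

The simulator realizes the renewal model cell by cell with known ground
truth, serving both as the package's fixture source and as the
independent oracle for the convolution machinery: each founder lineage
is assigned to the bulk or slow population (Bernoulli with the slow
mixing fraction), accumulates independent shifted-gamma inter-division
times until the chase time is exceeded, and records its completed
division count.

One representative is tracked per founder lineage, so division counts
sample the per-lineage generation probabilities ``H_n - H_{n+1}``
directly; expected *cell* numbers follow from the ``2**n`` descendant
weighting rather than from simulating exponentially many agents.

Readout: the day-0 intensity is lognormal, each division halves the
true intensity, measurement adds multiplicative lognormal noise, and a
hard autofluorescence floor clips what the instrument can see.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .intensity import IntensityHistogram, MixtureParams, mix_intensities
from .kinetics import DivisionTimeModel, MAX_GENERATIONS

__all__ = [
    "SimulationConfig",
    "DEFAULT_PARAMS",
    "simulate_divisions",
    "simulate_readout",
    "simulate_experiment",
    "export_experiment",
    "generation_fraction_table",
    "population_mixture_histogram",
]

#: Study-like truth: a fast-cycling bulk (mean cycle 23 h, typical of
#: colorectal cancer lines) and a rare slowly cycling population with a
#: roughly 3-fold longer mean cycle, mixed at 1.5%.
DEFAULT_PARAMS = MixtureParams(
    bulk=DivisionTimeModel(min_cycle_time=15.0, shape=2.0, scale=4.0),
    slow=DivisionTimeModel(min_cycle_time=60.0, shape=2.0, scale=6.0),
    slow_fraction=0.015,
)

#: Default day-0 staining: median intensity 1e4 a.u. on a tight
#: lognormal peak.
DEFAULT_INIT_LOG_MEAN = float(np.log(1e4))
DEFAULT_INIT_LOG_SD = 0.4


@dataclass(frozen=True)
class SimulationConfig:
    """Ground-truth configuration of one simulated dye-dilution run.

    ``chase_times`` are in hours; a day-0 sample (chase time 0) is the
    conventional first entry, mirroring the label-then-chase design.
    ``measurement_cv`` is the coefficient of variation of the
    multiplicative lognormal measurement noise; the autofluorescence
    floor defaults to 1% of the day-0 median intensity.
    """

    seed: int
    n_cells: int = 100_000
    params: MixtureParams = DEFAULT_PARAMS
    chase_times: tuple = (0.0, 144.0)
    init_log_mean: float = DEFAULT_INIT_LOG_MEAN
    init_log_sd: float = DEFAULT_INIT_LOG_SD
    autofluorescence_floor: float | None = None
    measurement_cv: float = 0.15

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if any(t < 0 for t in self.chase_times):
            raise ValueError("chase_times must be >= 0")
        if self.measurement_cv < 0:
            raise ValueError("measurement_cv must be >= 0")
        if self.init_log_sd <= 0:
            raise ValueError("init_log_sd must be > 0")

    @property
    def floor(self) -> float:
        if self.autofluorescence_floor is not None:
            return self.autofluorescence_floor
        return 0.01 * float(np.exp(self.init_log_mean))


def _division_counts(model: DivisionTimeModel, n: int, chase_times: np.ndarray,
                     rng: np.random.Generator) -> np.ndarray:
    """Completed divisions of ``n`` lineages at each chase time.

    Inter-division times are accumulated lineage by lineage (vectorized
    over lineages) until every lineage has passed the last chase time.
    """
    t_max = chase_times.max()
    counts = np.zeros((n, chase_times.size), dtype=np.int64)
    elapsed = np.zeros(n)
    active = np.arange(n)
    for _ in range(MAX_GENERATIONS):
        if active.size == 0:
            break
        elapsed[active] += model.rvs(active.size, rng)
        counts[active] += (elapsed[active, None] <= chase_times[None, :])
        active = active[elapsed[active] <= t_max]
    return counts


def simulate_divisions(config: SimulationConfig,
                       rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Simulate division counts for every founder lineage.

    Returns a tidy frame with one row per (lineage, chase time):
    columns ``cell_id``, ``population`` ('bulk'/'slow'), ``chase_time``
    and ``divisions``.  Reproducible given the config seed.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_cells
    times = np.asarray(config.chase_times, dtype=float)
    is_slow = rng.random(n) < config.params.slow_fraction
    counts = np.zeros((n, times.size), dtype=np.int64)
    for slow, model in ((False, config.params.bulk), (True, config.params.slow)):
        idx = np.nonzero(is_slow == slow)[0]
        if idx.size:
            counts[idx] = _division_counts(model, idx.size, times, rng)
    frames = []
    for j, t in enumerate(times):
        frames.append(pd.DataFrame({
            "cell_id": np.arange(n),
            "population": np.where(is_slow, "slow", "bulk"),
            "chase_time": t,
            "divisions": counts[:, j],
        }))
    return pd.concat(frames, ignore_index=True)


def simulate_readout(cells: pd.DataFrame, config: SimulationConfig,
                     rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Fill per-cell true and measured intensities.

    The day-0 intensity is drawn once per lineage and shared across
    chase times; measurement noise is independent per readout.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    cells = cells.copy()
    n = int(cells["cell_id"].max()) + 1
    i0 = np.exp(rng.normal(config.init_log_mean, config.init_log_sd, size=n))
    true = i0[cells["cell_id"].to_numpy()] / 2.0 ** cells["divisions"].to_numpy()
    if config.measurement_cv > 0:
        noise_sd = np.sqrt(np.log1p(config.measurement_cv ** 2))
        measured = true * np.exp(rng.normal(0.0, noise_sd, size=true.size))
    else:
        measured = true.copy()
    cells["true_intensity"] = true
    cells["measured_intensity"] = np.maximum(measured, config.floor)
    return cells


def simulate_experiment(config: SimulationConfig) -> pd.DataFrame:
    """Divisions plus readout in one call, fully seeded by the config."""
    rng = np.random.default_rng(config.seed)
    cells = simulate_divisions(config, rng)
    return simulate_readout(cells, config, rng)


def _time_tag(t: float) -> str:
    return f"{t:g}h".replace(".", "p")


def export_experiment(cells: pd.DataFrame, out_dir, fmt: str = "csv") -> list[Path]:
    """Write per-chase-time event files (``cell_id,intensity``) and
    ground-truth sidecars (``cell_id,population,divisions``).

    Returns the list of written paths.  CSV is the canonical dialect.
    """
    if fmt != "csv":
        raise ValueError(f"unsupported export format {fmt!r}; use 'csv'")
    if "measured_intensity" not in cells:
        raise ValueError("intensities not filled; run simulate_readout first")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for t, group in cells.groupby("chase_time", sort=True):
        tag = _time_tag(float(t))
        events = out_dir / f"events_{tag}.csv"
        group.rename(columns={"measured_intensity": "intensity"})[
            ["cell_id", "intensity"]].to_csv(events, index=False)
        truth = out_dir / f"ground_truth_{tag}.csv"
        group[["cell_id", "population", "divisions"]].to_csv(truth, index=False)
        paths += [events, truth]
    return paths


def generation_fraction_table(cells: pd.DataFrame, chase_time: float,
                              weighting: str = "cells") -> np.ndarray:
    """Empirical generation occupancy at one chase time.

    ``weighting='cells'`` weights each lineage by its ``2**n``
    descendants (the Monte-Carlo estimate of the expected cell-number
    fractions ``N_n / sum N_m``); ``weighting='lineages'`` estimates the
    per-lineage probabilities ``H_n - H_{n+1}``.
    """
    sub = cells[cells["chase_time"] == chase_time]
    if sub.empty:
        raise ValueError(f"no cells at chase_time {chase_time}")
    n = sub["divisions"].to_numpy()
    if weighting == "cells":
        w = 2.0 ** n
    elif weighting == "lineages":
        w = np.ones_like(n, dtype=float)
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    out = np.bincount(n, weights=w)
    return out / out.sum()


def population_mixture_histogram(cells: pd.DataFrame, bin_edges: np.ndarray,
                                 chase_time: float, slow_fraction: float,
                                 column: str = "true_intensity") -> IntensityHistogram:
    """Monte-Carlo estimate of the model's normalized mixture histogram.

    Each population's histogram is built with per-lineage weights
    ``2**divisions`` (descendant counts), normalized separately, and the
    two are mixed with the given slow fraction — the empirical analogue
    of the normalized per-population prediction and its weighted
    mixture.  Intensities are clipped into the bin range so mass diluted
    below the floor lands in the first bin, matching the forward model.
    """
    sub = cells[cells["chase_time"] == chase_time]
    if sub.empty:
        raise ValueError(f"no cells at chase_time {chase_time}")
    log_edges = np.log(np.asarray(bin_edges, dtype=float))
    parts = {}
    for pop, grp in sub.groupby("population"):
        x = np.clip(np.log(grp[column].to_numpy()),
                    log_edges[0], np.nextafter(log_edges[-1], -np.inf))
        w = 2.0 ** grp["divisions"].to_numpy()
        mass, _ = np.histogram(x, bins=log_edges, weights=w)
        dens = mass / mass.sum() / np.diff(log_edges)
        parts[pop] = IntensityHistogram(bin_edges=np.asarray(bin_edges, float),
                                        density=dens, total_events=len(grp))
    if "slow" not in parts:
        return parts["bulk"]
    if "bulk" not in parts:
        return parts["slow"]
    return mix_intensities(parts["bulk"], parts["slow"], slow_fraction)
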