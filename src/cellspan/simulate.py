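"""Stochastic generator of synthetic mother-cell life histories.

Emulates the structure of microfluidic replicative-aging cohorts of
budding yeast so the full analysis pipeline can run, and be validated
against known ground truth, without external data:

* lifespans follow a discretized log-normal (sigmoidal survival curve,
  median ~16 divisions, range roughly 6-33 in a cohort of ~120 cells);
* each cell grows near-linearly in clock time at its own rate g_i
  (μm²/h), from a log-normal starting area with median ~17.65 μm²;
* each cell divides on its own base cell-cycle duration τ_i, jittered on
  the 20-minute imaging frame grid; after the Senescence Entry Point
  (a fixed fraction of the lifespan) cycle durations compound by a
  slowdown factor per division, so per-division size jumps grow late in
  life even though growth per hour does not;
* lifespan couples negatively to the per-division size increase g_i·τ_i
  (coupling κ acts on its logarithm, leaving starting size uncorrelated
  with lifespan);
* an optional fluorescence reporter dilutes in enlarging cells
  (concentration ~ production / (1 + δ·min(fold − 1, cap))) while production
  drifts up with elapsed time and surges per post-SEP division, so the
  total amount rises with age and senescent cells run reporter-rich; a
  late-life production→lifespan coupling makes high-reporter cells die
  sooner among the otherwise long-lived, mirroring ribosome-load effects
  that surface only once short-lived cells have left the population.

All randomness flows from one integer seed; a fixed seed reproduces the
cohort bit-identically.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .lifehistory import CellLifeHistory, LifeHistoryDataset

__all__ = ["SyntheticConfig", "generate_population", "truth_table"]

FRAME_HOURS = 1.0 / 3.0  # 20-minute imaging cadence


@dataclass
class SyntheticConfig:
    """Parameters of the life-history generator.

    Scale parameters are medians of log-normal draws; ``*_sdlog`` values
    are the standard deviations of the underlying normals.  Defaults are
    calibrated to a wild-type cohort: median lifespan about 16 divisions,
    starting areas with median 17.65 μm², a median fold-increase near 1.2
    by age 5, and a weak (~ -0.2) negative correlation between early size
    increase and lifespan.
    """

    n_cells: int = 119
    seed: int = 0

    # starting cross-sectional area, μm²
    start_size_median: float = 17.65
    start_size_sdlog: float = 0.18

    # growth rate g_i, μm²/hour (near-constant in time within a life)
    growth_rate_median: float = 0.55
    growth_rate_sdlog: float = 0.5

    # base cell-cycle duration τ_i, hours, and multiplicative per-division jitter
    base_cycle_median: float = 1.5
    base_cycle_sdlog: float = 0.20
    cycle_jitter_sdlog: float = 0.12

    # replicative lifespan: discretized log-normal with couplings
    lifespan_median: float = 16.0
    lifespan_sdlog: float = 0.30
    lifespan_coupling: float = 0.16   # κ ≥ 0: on log per-division size increase
    rls_floor: int = 3

    # senescence entry point
    sep_fraction: float = 0.75        # fraction of lifespan at which SEP occurs
    post_sep_slowdown: float = 1.4    # cycle-duration multiplier per post-SEP division

    # measurement noise on sizes, μm²
    size_noise_sd: float = 0.5

    # fluorescence reporter
    include_fluor: bool = True
    fluor_production_median: float = 100.0  # AU, per-cell baseline concentration
    fluor_production_sdlog: float = 0.10
    fluor_dilution: float = 4.0             # δ ≥ 0: concentration dilution with fold
    fluor_dilution_cap: float = 0.7         # fold−1 beyond which dilution saturates
    fluor_time_slope: float = 0.02          # fractional production rise per hour
    fluor_sep_surge: float = 1.7            # production multiplier per post-SEP division
    # late-life coupling: high production shortens lifespan, but only for
    # cells whose baseline lifespan draw is above the population median —
    # a reporter-load mortality channel that short-lived cells never reach
    fluor_lifespan_coupling: float = 1.5
    fluor_noise_sd: float = 2.0             # AU measurement noise

    def validate(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        for name in (
            "start_size_median", "growth_rate_median", "base_cycle_median",
            "lifespan_median", "fluor_production_median", "post_sep_slowdown",
            "fluor_sep_surge",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in (
            "start_size_sdlog", "growth_rate_sdlog", "base_cycle_sdlog",
            "cycle_jitter_sdlog", "lifespan_sdlog", "lifespan_coupling",
            "size_noise_sd", "fluor_production_sdlog", "fluor_dilution",
            "fluor_time_slope", "fluor_lifespan_coupling", "fluor_noise_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0.0 < self.sep_fraction <= 1.0:
            raise ValueError("sep_fraction must lie in (0, 1]")
        if self.rls_floor < 1:
            raise ValueError("rls_floor must be >= 1")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticConfig":
        return cls(**d)


def _snap_to_grid(duration: float) -> float:
    """Round a cycle duration to the 20-minute frame grid, minimum one frame."""
    return max(FRAME_HOURS, round(duration / FRAME_HOURS) * FRAME_HOURS)


def _simulate(config: SyntheticConfig) -> tuple[list[CellLifeHistory], pd.DataFrame]:
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_cells

    s0 = config.start_size_median * np.exp(rng.normal(0, config.start_size_sdlog, n))
    g = config.growth_rate_median * np.exp(rng.normal(0, config.growth_rate_sdlog, n))
    tau = config.base_cycle_median * np.exp(rng.normal(0, config.base_cycle_sdlog, n))
    prod = config.fluor_production_median * np.exp(
        rng.normal(0, config.fluor_production_sdlog, n)
    )

    # lifespan: log-median shifted down by κ·(log per-division increase,
    # centred) so the median stays put; the reporter-load penalty applies
    # only above the baseline median (a late-life mortality channel)
    log_gain = np.log(g * tau) - np.log(config.growth_rate_median * config.base_cycle_median)
    log_prod = np.log(prod) - np.log(config.fluor_production_median)
    mu = np.log(config.lifespan_median) - config.lifespan_coupling * log_gain
    log_rls = rng.normal(mu, config.lifespan_sdlog)
    if config.include_fluor and config.fluor_lifespan_coupling > 0:
        # reporter-load penalty grows with how far the baseline draw sits
        # above half the median lifespan: cells dying young never feel it,
        # and the longer a cell would otherwise live the more its lifespan
        # reflects reporter load
        late = np.maximum(0.0, log_rls - np.log(0.5 * config.lifespan_median))
        # one-sided: reporter load above the population norm costs divisions,
        # but low load never extends life (keeps the lifespan range realistic)
        log_rls = log_rls - config.fluor_lifespan_coupling * late * np.maximum(log_prod, 0.0)
    rls = np.maximum(config.rls_floor, np.rint(np.exp(log_rls))).astype(int)

    cells: list[CellLifeHistory] = []
    truth_rows = []
    for i in range(n):
        L = int(rls[i])
        sep = int(round(config.sep_fraction * L)) if L >= 4 else None
        if sep is not None:
            sep = min(max(sep, 2), L - 1)  # keep the elbow interior to the profile
        # durations of cycles 1..L-1 (between consecutive recorded G1s)
        durations = np.empty(max(L - 1, 0))
        for k in range(1, L):
            jitter = np.exp(rng.normal(0, config.cycle_jitter_sdlog))
            d = tau[i] * jitter
            if sep is not None and k >= sep:
                d *= config.post_sep_slowdown ** (k - sep + 1)
            durations[k - 1] = _snap_to_grid(d)
        times = np.concatenate([[0.0], np.cumsum(durations)])

        sizes = s0[i] + g[i] * times + rng.normal(0, config.size_noise_sd, L)
        sizes = np.maximum(sizes, 0.2 * s0[i])  # noise cannot push area near zero

        fluor = None
        if config.include_fluor:
            fold = sizes / sizes[0]
            k_ages = np.arange(1, L + 1)
            post = np.maximum(0, k_ages - sep + 1) if sep is not None else np.zeros(L)
            production = (
                prod[i]
                * (1.0 + config.fluor_time_slope * times)
                * config.fluor_sep_surge ** post
            )
            enlargement = np.clip(fold - 1.0, 0.0, config.fluor_dilution_cap)
            conc = production / (1.0 + config.fluor_dilution * enlargement)
            fluor = np.maximum(conc + rng.normal(0, config.fluor_noise_sd, L), 0.0)

        cid = f"synth{i + 1:04d}"
        cells.append(
            CellLifeHistory(
                cell_id=cid,
                experiment_id="synthetic",
                sizes=sizes,
                times=times,
                avg_fluor=fluor,
                death_observed=True,
            )
        )
        truth_rows.append(
            {
                "cell_id": cid,
                "growth_rate": g[i],
                "base_cycle": tau[i],
                "rls": L,
                "sep_age": sep,
                "start_size": s0[i],
                "production": prod[i] if config.include_fluor else np.nan,
            }
        )
    return cells, pd.DataFrame(truth_rows)


def generate_population(config: SyntheticConfig) -> LifeHistoryDataset:
    """Generate a cohort of synthetic life histories.

    Deterministic for a fixed ``config.seed``; every generated cell
    satisfies the life-history invariants (positive sizes, strictly
    increasing times, matched series lengths).
    """
    cells, _ = _simulate(config)
    return LifeHistoryDataset(cells=cells, name=f"synthetic(seed={config.seed})", source="synthetic")


def truth_table(config: SyntheticConfig, dataset: LifeHistoryDataset) -> pd.DataFrame:
    """Ground-truth parameters (g_i, τ_i, RLS, SEP age, ...) aligned to a dataset.

    Re-simulates from ``config`` and verifies the ids match the dataset
    row for row, so truth and observations cannot drift apart.
    """
    cells, truth = _simulate(config)
    ids = list(truth["cell_id"])
    if ids != dataset.cell_ids:
        raise ValueError("dataset does not match this config/seed (cell id mismatch)")
    for ours, theirs in zip(cells, dataset.cells):
        if ours.rls != theirs.rls or not np.array_equal(ours.sizes, theirs.sizes):
            raise ValueError(
                f"dataset does not match this config/seed (cell {theirs.cell_id!r} differs)"
            )
    return truth.set_index("cell_id")
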