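"""Simulation of seasonal pitfall-trap catches.

The generator emulates a season of pitfall trapping for a spring-active
carabid beetle.  The design is 3 abundance treatments (multipliers 1x, 2x,
4x) x 5 replicate plots x 4 traps, with traps emptied at five 20-day
intervals over a 100-day season — 300 trap-interval observations in all.

Counts arise from a Poisson log-normal process: each replicate plot
carries one normal random effect (SD ``site_sd``) on the log scale, each
trap one additional effect (SD ``trap_sd``); the Poisson rate of a trap
in an interval is the fixed seasonal mean multiplied by the exponential
of these effects.  Seasonal activity enters only through the fixed
profile of catch proportions per interval (default 25/49/13/9/4 %); the
random effects are drawn once and held constant across intervals, since
a physical plot or trap has one persistent peculiarity.

No log-normal mean correction (-sigma^2/2) is applied to the rate, which
is the standard GLMM formulation; consequently the realised expected
catch exceeds the nominal per-trap mean by the factor
``exp((site_sd^2 + trap_sd^2)/2)`` (about 5.6 % at the field-data SDs of
0.14 and 0.30).  :func:`expected_cell_catch` deliberately reports the
pre-random-effect expectation — the design-table values.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "SeasonalProfile",
    "SimulationParams",
    "Dataset",
    "SimulationError",
    "PARAMETER_SETS",
    "expected_cell_catch",
    "expected_table",
    "simulate_dataset",
    "simulate_batch",
    "dataset_seed",
    "read_observations",
    "params_from_config",
]

_DEFAULT_PROPORTIONS = (0.25, 0.49, 0.13, 0.09, 0.04)

#: column order of the long-format observation table
OBS_COLUMNS = ("treatment", "replicate", "trap", "interval", "count", "trap_days", "lost")


class SimulationError(RuntimeError):
    """Raised when the simulated Poisson rates are not finite."""


@dataclass(frozen=True)
class SeasonalProfile:
    """Fixed fractions of the season's catch expected in each 20-day interval.

    Exactly five entries, each in [0, 1], summing to one.  Zero entries are
    permitted for degenerate profiles (all activity in one interval), but
    models that take the profile as a log offset reject them.
    """

    proportions: tuple[float, ...] = _DEFAULT_PROPORTIONS

    def __post_init__(self) -> None:
        props = tuple(float(p) for p in self.proportions)
        object.__setattr__(self, "proportions", props)
        if len(props) != 5:
            raise ValueError(f"seasonal profile needs exactly 5 proportions, got {len(props)}")
        if any(p < 0.0 or p > 1.0 for p in props):
            raise ValueError("seasonal proportions must lie in [0, 1]")
        if abs(sum(props) - 1.0) > 1e-9:
            raise ValueError(f"seasonal proportions must sum to 1, got {sum(props)!r}")

    @property
    def percents(self) -> tuple[float, ...]:
        """Proportions expressed as percentages (25, 49, ...)."""
        return tuple(100.0 * p for p in self.proportions)

    def __len__(self) -> int:
        return len(self.proportions)


@dataclass(frozen=True)
class SimulationParams:
    """Parameters of one simulated trapping study.

    ``mean_catch_t1`` is the expected season-total catch per trap in
    Treatment 1 (individuals/trap over 100 days); treatments 2 and 3 are
    scaled by ``treatment_multipliers``.  ``site_sd`` and ``trap_sd`` are
    the log-scale SDs of the replicate-plot and trap random effects.
    """

    mean_catch_t1: float = 1.47
    treatment_multipliers: tuple[float, ...] = (1.0, 2.0, 4.0)
    site_sd: float = 0.14
    trap_sd: float = 0.30
    n_replicates: int = 5
    n_traps: int = 4
    n_intervals: int = 5
    interval_days: float = 20.0
    seasonal_profile: SeasonalProfile = field(default_factory=SeasonalProfile)

    def __post_init__(self) -> None:
        if self.mean_catch_t1 <= 0:
            raise ValueError("mean_catch_t1 must be positive")
        if self.site_sd < 0 or self.trap_sd < 0:
            raise ValueError("random-effect SDs must be non-negative")
        if min(self.n_replicates, self.n_traps, self.n_intervals) < 1:
            raise ValueError("design dimensions must be at least 1")
        if self.interval_days <= 0:
            raise ValueError("interval_days must be positive")
        if any(m <= 0 for m in self.treatment_multipliers):
            raise ValueError("treatment multipliers must be positive")
        if self.n_intervals != len(self.seasonal_profile):
            raise ValueError("n_intervals must match the seasonal profile length")
        object.__setattr__(
            self, "treatment_multipliers", tuple(float(m) for m in self.treatment_multipliers)
        )

    @property
    def n_treatments(self) -> int:
        return len(self.treatment_multipliers)

    @property
    def n_observations(self) -> int:
        return self.n_treatments * self.n_replicates * self.n_traps * self.n_intervals


_S5 = math.sqrt(5.0)

#: the seven named parameter sets of the simulation study: the field-data
#: baseline (mean 1.47, site SD 0.14, trap SD 0.30) and x5 / /5 perturbations
#: of the mean and of each squared SD.
PARAMETER_SETS: dict[str, SimulationParams] = {
    "field": SimulationParams(),
    "low_mean": SimulationParams(mean_catch_t1=1.47 / 5.0),
    "high_mean": SimulationParams(mean_catch_t1=1.47 * 5.0),
    "lo_site_lo_trap": SimulationParams(site_sd=0.14 / _S5, trap_sd=0.30 / _S5),
    "lo_site_hi_trap": SimulationParams(site_sd=0.14 / _S5, trap_sd=0.30 * _S5),
    "hi_site_lo_trap": SimulationParams(site_sd=0.14 * _S5, trap_sd=0.30 / _S5),
    "hi_site_hi_trap": SimulationParams(site_sd=0.14 * _S5, trap_sd=0.30 * _S5),
}


@dataclass
class Dataset:
    """One simulated trapping season as a long-format observation table."""

    observations: pd.DataFrame
    params: SimulationParams
    seed: int

    @property
    def has_losses(self) -> bool:
        return bool(self.observations["lost"].any())

    def surviving(self) -> pd.DataFrame:
        """Observations from traps that were recovered (not lost)."""
        return self.observations[~self.observations["lost"]]

    def copy(self) -> "Dataset":
        return Dataset(self.observations.copy(), self.params, self.seed)

    def to_csv(self, path) -> None:
        self.observations.to_csv(path, index=False, columns=list(OBS_COLUMNS))


def read_observations(path) -> pd.DataFrame:
    """Read a long-format observation CSV written by :meth:`Dataset.to_csv`."""
    df = pd.read_csv(path)
    missing = set(OBS_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"observation table missing columns: {sorted(missing)}")
    df["lost"] = df["lost"].astype(bool)
    return df[list(OBS_COLUMNS)]


def expected_cell_catch(params: SimulationParams, treatment: int, interval: int) -> float:
    """Expected total catch of one treatment in one interval, summed over all
    its traps, before random effects are applied.

    ``treatment`` and ``interval`` are 1-based design labels.  Rounding the
    field-data values to one decimal reproduces the study's design table.
    """
    if not 1 <= treatment <= params.n_treatments:
        raise IndexError(f"treatment label {treatment} out of range 1..{params.n_treatments}")
    if not 1 <= interval <= params.n_intervals:
        raise IndexError(f"interval label {interval} out of range 1..{params.n_intervals}")
    per_trap_season = params.mean_catch_t1 * params.treatment_multipliers[treatment - 1]
    n_traps_total = params.n_replicates * params.n_traps
    return per_trap_season * n_traps_total * params.seasonal_profile.proportions[interval - 1]


def expected_table(params: SimulationParams) -> pd.DataFrame:
    """Expected catch per treatment x interval plus season totals, as a frame
    with intervals as rows and treatments as columns."""
    data = {
        t: [expected_cell_catch(params, t, i) for i in range(1, params.n_intervals + 1)]
        for t in range(1, params.n_treatments + 1)
    }
    df = pd.DataFrame(data, index=[f"interval_{i}" for i in range(1, params.n_intervals + 1)])
    df.columns = [f"treatment_{t}" for t in df.columns]
    df.loc["total"] = df.sum(axis=0)
    return df


def simulate_dataset(params: SimulationParams, seed: int) -> Dataset:
    """Draw one complete dataset (no losses) from the Poisson log-normal process.

    One site effect ~ N(0, site_sd^2) per (treatment, replicate) and one trap
    effect ~ N(0, trap_sd^2) per (treatment, replicate, trap) are drawn on the
    log scale and held constant across intervals.  The count of trap *k* in
    interval *i* is Poisson with rate
    ``mean_catch_t1 * multiplier_t * proportion_i * exp(site + trap)``.
    Identical seeds give identical datasets.
    """
    rng = np.random.default_rng(seed)
    nt, nr, nk, ni = params.n_treatments, params.n_replicates, params.n_traps, params.n_intervals
    site = rng.normal(0.0, params.site_sd, size=(nt, nr))
    trap = rng.normal(0.0, params.trap_sd, size=(nt, nr, nk))
    mult = np.asarray(params.treatment_multipliers, dtype=float)
    props = np.asarray(params.seasonal_profile.proportions, dtype=float)
    base = params.mean_catch_t1 * mult[:, None, None, None] * props[None, None, None, :]
    rate = base * np.exp(site[:, :, None, None] + trap[:, :, :, None])
    if not np.all(np.isfinite(rate)):
        raise SimulationError("non-finite Poisson rate encountered")
    counts = rng.poisson(rate)
    t_ix, r_ix, k_ix, i_ix = np.indices((nt, nr, nk, ni))
    obs = pd.DataFrame(
        {
            "treatment": t_ix.ravel() + 1,
            "replicate": r_ix.ravel() + 1,
            "trap": k_ix.ravel() + 1,
            "interval": i_ix.ravel() + 1,
            "count": counts.ravel(),
            "trap_days": params.interval_days,
            "lost": False,
        }
    )
    return Dataset(obs, params, int(seed))


def dataset_seed(master_seed: int, index: int) -> int:
    """Stable per-dataset seed derived from (master seed, dataset index)."""
    ss = np.random.SeedSequence((int(master_seed), int(index)))
    return int(ss.generate_state(1)[0])


def simulate_batch(params: SimulationParams, n_sims: int = 100, master_seed: int = 0) -> list[Dataset]:
    """Simulate ``n_sims`` independent datasets with deterministically derived
    per-dataset seeds, so any one dataset can be replayed from its seed."""
    if n_sims < 1:
        raise ValueError("n_sims must be at least 1")
    return [simulate_dataset(params, dataset_seed(master_seed, i)) for i in range(n_sims)]


def params_from_config(path, name: str) -> SimulationParams:
    """Build a parameter set from a YAML file.

    The file maps parameter-set names to field overrides of
    :class:`SimulationParams`, e.g.::

        field: {mean_catch_t1: 1.47, site_sd: 0.14, trap_sd: 0.30}
        low_mean: {mean_catch_t1: 0.294}

    A ``seasonal_profile`` entry may be given as a list of five proportions.
    """
    with open(path) as fh:
        config = yaml.safe_load(fh)
    if name not in config:
        raise KeyError(f"parameter set {name!r} not found in {path}")
    entry = dict(config[name] or {})
    if "seasonal_profile" in entry:
        entry["seasonal_profile"] = SeasonalProfile(tuple(entry["seasonal_profile"]))
    if "treatment_multipliers" in entry:
        entry["treatment_multipliers"] = tuple(entry["treatment_multipliers"])
    valid = {f.name for f in dataclasses.fields(SimulationParams)}
    unknown = set(entry) - valid
    if unknown:
        raise ValueError(f"unknown parameter fields: {sorted(unknown)}")
    return SimulationParams(**entry)
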