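"""Trap-loss manipulation of simulated datasets.

Losses are concentrated in design cells where they bias the traditional
standardization most: the *high-catch* scenario removes traps from the
high-abundance treatments (2, 3) during the high-activity intervals (1, 2);
the *low-catch* scenario from the low-abundance treatments (1, 2) during
the low-activity intervals (4, 5).  Either block holds 80 of the 300
observations (2 treatments x 2 intervals x 5 replicates x 4 traps), and the
four loss severities remove exactly 18.75 %, 37.5 %, 56.25 % or 75 % of it
— 15, 30, 45 or 60 points, i.e. 5–20 % of the whole design.  The *random*
scenario removes the same four totals drawn uniformly from all 300 points.

A fixed number of points is sampled without replacement (not per-point
Bernoulli), so the stated totals are exact.  Lost observations are flagged
rather than deleted; every downstream computation treats flagged rows as
absent (they contribute neither counts nor trap-days).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .simulate import Dataset, SimulationParams

__all__ = ["LossScenario", "SEVERITIES", "OVERALL_PERCENTS", "n_lost", "apply_loss"]

#: within-block loss fractions used in the study
SEVERITIES = (0.0, 0.1875, 0.375, 0.5625, 0.75)

#: loss expressed as % of the whole 300-point design -> within-block fraction
OVERALL_PERCENTS = {0: 0.0, 5: 0.1875, 10: 0.375, 15: 0.5625, 20: 0.75}

_KINDS = ("high_catch", "low_catch", "random", "none")


@dataclass(frozen=True)
class LossScenario:
    """Which design cells lose traps, and how severely.

    ``within_cell_fraction`` is the fraction of the 80-point eligible block
    removed (one of 0, 0.1875, 0.375, 0.5625, 0.75); for ``random`` the same
    number of points is removed from the whole design.
    """

    kind: str
    within_cell_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown loss kind {self.kind!r}; expected one of {_KINDS}")
        if not any(np.isclose(self.within_cell_fraction, s) for s in SEVERITIES):
            raise ValueError(
                f"within_cell_fraction must be one of {SEVERITIES}, got {self.within_cell_fraction}"
            )
        if self.kind == "none" and self.within_cell_fraction != 0.0:
            raise ValueError("kind 'none' requires within_cell_fraction 0")

    @classmethod
    def from_overall_percent(cls, kind: str, percent: int) -> "LossScenario":
        """Build a scenario from the overall design-loss percent (0/5/10/15/20)."""
        if percent not in OVERALL_PERCENTS:
            raise ValueError(f"overall loss percent must be one of {sorted(OVERALL_PERCENTS)}")
        return cls(kind=kind, within_cell_fraction=OVERALL_PERCENTS[percent])

    def eligible_cells(self, params: SimulationParams | None = None) -> frozenset[tuple[int, int]]:
        """(treatment, interval) cells from which traps may be lost.

        For ``random`` every cell is eligible; for ``none`` no cell is.
        """
        params = params or SimulationParams()
        all_cells = frozenset(
            (t, i)
            for t in range(1, params.n_treatments + 1)
            for i in range(1, params.n_intervals + 1)
        )
        if self.kind == "high_catch":
            return frozenset({(2, 1), (2, 2), (3, 1), (3, 2)})
        if self.kind == "low_catch":
            return frozenset({(1, 4), (1, 5), (2, 4), (2, 5)})
        if self.kind == "random":
            return all_cells
        return frozenset()


def n_lost(scenario: LossScenario, params: SimulationParams | None = None) -> int:
    """Number of observations removed under a scenario.

    The severity always refers to the 80-point block (4 cells x replicates x
    traps), so the four nonzero severities remove exactly 15, 30, 45 and 60
    points — also for the ``random`` scenario, which draws the same totals
    from the whole design.
    """
    if scenario.kind == "none":
        return 0
    params = params or SimulationParams()
    block = 4 * params.n_replicates * params.n_traps
    return int(round(scenario.within_cell_fraction * block))


def apply_loss(dataset: Dataset, scenario: LossScenario, seed: int) -> Dataset:
    """Flag ``n_lost`` observations, sampled uniformly without replacement
    from the scenario's eligible pool, as lost.  Deterministic given ``seed``;
    counts of surviving observations are untouched."""
    if dataset.has_losses:
        raise ValueError("dataset already has losses applied")
    out = dataset.copy()
    n = n_lost(scenario, dataset.params)
    if n == 0:
        return out
    obs = out.observations
    if scenario.kind == "random":
        pool = obs.index.to_numpy()
    else:
        cells = scenario.eligible_cells(dataset.params)
        keys = list(zip(obs["treatment"], obs["interval"]))
        mask = np.array([k in cells for k in keys])
        pool = obs.index.to_numpy()[mask]
    if n > len(pool):
        raise ValueError(f"cannot lose {n} observations from a pool of {len(pool)}")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(pool, size=n, replace=False)
    obs.loc[chosen, "lost"] = True
    return out
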