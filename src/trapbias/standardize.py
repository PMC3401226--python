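"""Traditional catch standardization to 100 trapping days.

The common practice in the pitfall-trapping literature: sum a replicate's
catch over its traps and intervals, divide by the trap-days actually
accumulated by recovered traps (400 per replicate when nothing is lost),
and multiply by 100.  Seasonal activity is deliberately ignored — that is
the point of evaluating this procedure.
"""

from __future__ import annotations

import itertools

import pandas as pd

from .simulate import Dataset

__all__ = ["StandardizationError", "summarize_replicates"]


class StandardizationError(ValueError):
    """A replicate has no surviving trap-days, so its catch cannot be standardized."""


def summarize_replicates(dataset: Dataset) -> pd.DataFrame:
    """One row per (treatment, replicate): total surviving catch, surviving
    trap-days, and the catch standardized to 100 trap-days.

    Lost observations are excluded from both the numerator (catch) and the
    denominator (trap-days).
    """
    p = dataset.params
    alive = dataset.surviving()
    grouped = alive.groupby(["treatment", "replicate"]).agg(
        total_count=("count", "sum"), trap_days=("trap_days", "sum")
    )
    full_index = pd.MultiIndex.from_tuples(
        itertools.product(range(1, p.n_treatments + 1), range(1, p.n_replicates + 1)),
        names=["treatment", "replicate"],
    )
    grouped = grouped.reindex(full_index)
    if grouped["trap_days"].isna().any() or (grouped["trap_days"] <= 0).any():
        bad = grouped.index[grouped["trap_days"].isna() | (grouped["trap_days"] <= 0)]
        raise StandardizationError(
            f"replicates with zero surviving trap-days: {list(bad)}"
        )
    grouped["standardized_catch"] = grouped["total_count"] / grouped["trap_days"] * 100.0
    return grouped.reset_index()
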