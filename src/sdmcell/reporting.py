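"""Summary statistics over per-compound rejection tables.

Works on tables shaped like the packaged NF/RO fixtures: one row per
compound, one ``rejection_pct_*`` column per stirring speed, values in
percent. Internal aggregates stay unrounded; presentation rounds half-up
to two decimals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd


def round_half_up(x: float, decimals: int = 2) -> float:
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class SummaryReport:
    mean_rejection_pct: float  # grand mean over all cells, unrounded
    per_compound_pct: dict[str, float]
    per_condition_pct: dict[str, float]
    n_compounds: int
    n_cells: int
    metadata: dict = field(default_factory=dict)

    @property
    def mean_rejection_pct_rounded(self) -> float:
        return round_half_up(self.mean_rejection_pct, 2)

    def to_dict(self) -> dict:
        return {
            "mean_rejection_pct": self.mean_rejection_pct_rounded,
            "per_compound_pct": {
                k: round_half_up(v, 2) for k, v in self.per_compound_pct.items()
            },
            "per_condition_pct": {
                k: round_half_up(v, 2) for k, v in self.per_condition_pct.items()
            },
            "n_compounds": self.n_compounds,
            "n_cells": self.n_cells,
            **({"metadata": self.metadata} if self.metadata else {}),
        }


def summarize_rejections(table: pd.DataFrame, name_column: str = "name") -> SummaryReport:
    """Arithmetic mean over every (compound, condition) rejection cell.

    Also emits per-compound means (across conditions) and per-condition
    means (across compounds). Values must be percentages in [0, 100].
    """
    value_cols = [c for c in table.columns if c != name_column]
    if table.empty or not value_cols:
        raise ValueError("empty rejection table")
    values = table[value_cols].to_numpy(dtype=float)
    if np.any((values < 0) | (values > 100)):
        raise ValueError("rejection percentages must lie in [0, 100]")
    return SummaryReport(
        mean_rejection_pct=float(values.mean()),
        per_compound_pct={
            str(name): float(row.mean())
            for name, row in zip(table[name_column], values)
        },
        per_condition_pct={c: float(values[:, i].mean()) for i, c in enumerate(value_cols)},
        n_compounds=len(table),
        n_cells=int(values.size),
    )
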