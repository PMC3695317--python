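"""Pearson correlation between bin abundances and reactor performance.

Relates the relative abundance of chosen fragment bins (e.g., the two bands
of the dominant methanogen) to process parameters such as daily biogas and
methane volumes.  Significance is a two-sided t test with n - 2 degrees of
freedom at the conventional P < 0.05 level; samples without production data
(typically the inoculum) are excluded pairwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .peaks import BinTable

__all__ = ["CorrelationResult", "pearson", "correlate_bins"]

SIGNIFICANCE_LEVEL = 0.05


@dataclass(frozen=True)
class CorrelationResult:
    bin_id: str
    parameter: str
    Pc: float
    p_value: float
    n: int

    @property
    def significant(self) -> bool:
        return self.p_value < SIGNIFICANCE_LEVEL


def pearson(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Sample Pearson r and its two-sided p-value (t test, n - 2 df).

    Raises for mismatched lengths, n < 3 or zero variance in either variable
    (an undefined correlation is an error, never a silent NaN).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    n = x.size
    if n < 3:
        raise ValueError(f"need at least 3 paired observations, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def correlate_bins(
    bin_table: BinTable,
    parameters: pd.DataFrame,
    bin_ids: Sequence[float | int],
) -> list[CorrelationResult]:
    """Correlate chosen bins' relative abundances with each process parameter.

    ``parameters`` must carry a ``sample`` column (or index) and one numeric
    column per parameter; samples are aligned by label and rows with missing
    values are dropped pairwise, with the effective n reported per result.
    ``bin_ids`` may be bin indices (int) or approximate bin sizes in bp
    (float), resolved against the table's centers within its tolerance.
    """
    params = parameters.copy()
    if "sample" in params.columns:
        params = params.set_index("sample")
    params.index = params.index.astype(str)

    common = [s for s in bin_table.samples if s in params.index]
    if len(common) < 3:
        raise ValueError("fewer than 3 samples shared between bin table and parameters")
    sample_idx = {s: i for i, s in enumerate(bin_table.samples)}

    results: list[CorrelationResult] = []
    for bid in bin_ids:
        if isinstance(bid, (int, np.integer)) and not isinstance(bid, bool):
            b = int(bid)
            if not 0 <= b < len(bin_table.bin_centers):
                raise ValueError(f"bin index {b} out of range")
        else:
            b = bin_table.nearest_bin(float(bid))
            if b is None:
                raise ValueError(f"no bin within tolerance of {bid} bp")
        label = f"{bin_table.bin_centers[b]:.0f}bp"
        abundances = {s: bin_table.abundance[sample_idx[s], b] for s in common}
        for param in params.columns:
            col = pd.to_numeric(params[param], errors="coerce")
            pairs = [(abundances[s], col.loc[s]) for s in common if np.isfinite(col.loc[s])]
            if len(pairs) < 3:
                raise ValueError(
                    f"fewer than 3 complete (abundance, {param}) pairs after pairwise deletion"
                )
            x, y = zip(*pairs)
            r, p = pearson(x, y)
            results.append(
                CorrelationResult(bin_id=label, parameter=param, Pc=r, p_value=p, n=len(pairs))
            )
    return results
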