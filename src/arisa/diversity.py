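"""Shannon diversity of community fingerprints from peak heights.

The Shannon index is computed on densitometric peak heights,
``H' = -sum (n_i / N) log (n_i / N)`` with ``n_i`` one peak's height and
``N`` the sum of all peak heights in the profile.  Natural logarithm by
default (capillary profiles with ~30 peaks give H' around 3.5, consistent
with natural log); base-10 is available.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .models import Fingerprint

__all__ = ["DiversityResult", "shannon_index", "fingerprint_diversity", "diversity_table"]

_LOG = {"natural": math.log, "base10": math.log10}


@dataclass(frozen=True)
class DiversityResult:
    sample_label: str
    H: float
    n_bands: int
    log_base: str = "natural"


def shannon_index(
    heights: Sequence[float],
    log_base: str = "natural",
    sample_label: str = "",
) -> DiversityResult:
    """Shannon index H' from peak heights; zero heights are dropped first.

    Raises ``ValueError`` when no positive height remains — an empty lane has
    undefined diversity, which is distinct from the H' = 0 of a single band.
    """
    if log_base not in _LOG:
        raise ValueError(f"log_base must be one of {sorted(_LOG)}")
    h = np.asarray([x for x in heights if x > 0], dtype=float)
    if np.any(np.asarray(heights, dtype=float) < 0):
        raise ValueError("negative peak height")
    if h.size == 0:
        raise ValueError(f"no positive peak heights for {sample_label or 'sample'}")
    p = h / h.sum()
    log = _LOG[log_base]
    H = -float(sum(pi * log(pi) for pi in p))
    return DiversityResult(sample_label=sample_label, H=max(H, 0.0), n_bands=int(h.size), log_base=log_base)


def fingerprint_diversity(fingerprint: Fingerprint, log_base: str = "natural") -> DiversityResult:
    """Shannon index of one fingerprint's sample peaks (standards excluded)."""
    return shannon_index(
        [p.height for p in fingerprint.sample_peaks],
        log_base=log_base,
        sample_label=fingerprint.sample_label,
    )


def diversity_table(
    replicates: Mapping[str, Iterable[Fingerprint]] | Sequence[Fingerprint],
    log_base: str = "natural",
) -> pd.DataFrame:
    """Per-sample mean and standard deviation of H' across replicates.

    Accepts either a mapping sample -> replicate fingerprints or a flat
    sequence of fingerprints grouped by their sample labels.  With a single
    replicate the standard deviation is reported as missing, not zero.
    Columns: ``H_mean``, ``H_sd`` (sample standard deviation), ``n_replicates``,
    ``n_bands_mean``.
    """
    if not isinstance(replicates, Mapping):
        grouped: dict[str, list[Fingerprint]] = {}
        for fp in replicates:
            grouped.setdefault(fp.sample_label, []).append(fp)
        replicates = grouped
    rows = []
    for sample, fps in replicates.items():
        fps = list(fps)
        if not fps:
            raise ValueError(f"sample {sample!r} has no replicates")
        results = [fingerprint_diversity(fp, log_base=log_base) for fp in fps]
        hs = np.array([r.H for r in results])
        rows.append(
            {
                "sample": sample,
                "H_mean": float(hs.mean()),
                "H_sd": float(hs.std(ddof=1)) if hs.size > 1 else np.nan,
                "n_replicates": int(hs.size),
                "n_bands_mean": float(np.mean([r.n_bands for r in results])),
            }
        )
    return pd.DataFrame(rows).set_index("sample")
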