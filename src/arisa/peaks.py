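"""Peak-table processing: calibration, filtering and fragment-size binning.

Raw per-platform peak tables become a :class:`BinTable` — a samples x
size-bins matrix of presence and relative abundance — through four steps:

1. :func:`read_peak_tables` parses the delimited tables.
2. :func:`calibrate_sizes` remaps sizes against internal size standards by
   piecewise-linear interpolation.
3. :func:`filter_peaks` applies the platform detection threshold and the
   400–1000 bp spacer analysis window.
4. :func:`bin_peaks` groups fragment sizes across samples that lie within
   ±5 % of each other into shared bins and converts peak areas to relative
   abundance per sample.

The ±5 % equivalence rule is pairwise and therefore not transitive; binning
is resolved as the exact optimum over size-sorted contiguous partitions
under the rule "no bin spans more than the tolerance fraction of its
smallest member", minimising first the number of bins and then the total
within-bin spread (ties broken toward the lower bin).
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .models import Fingerprint, PeakRecord, Platform, PlatformModel, SizeWindow

__all__ = [
    "BinTable",
    "read_peak_tables",
    "calibrate_sizes",
    "filter_peaks",
    "bin_peaks",
    "band_richness",
    "optimal_partition",
    "write_bin_table",
    "read_bin_table",
]

REQUIRED_COLUMNS = ("sample", "platform", "size_bp", "height", "area", "is_standard")

_FILENAME_RE = re.compile(r"peaks_(gel|mf|ga)_(.+)\.[^.]+$")


@dataclass(frozen=True)
class BinTable:
    """Samples x size-bins matrix of presence and relative abundance.

    ``abundance`` rows sum to 1 for samples with at least one retained peak
    (all-zero rows mark empty samples); ``presence`` is simply
    ``abundance > 0``.  Adjacent bins are mutually non-equivalent: no two of
    them could be merged without some pair of members exceeding the
    tolerance.
    """

    bin_centers: tuple[float, ...]
    samples: tuple[str, ...]
    abundance: np.ndarray
    tolerance: float = 0.05
    platform: Platform | None = None

    def __post_init__(self) -> None:
        ab = np.asarray(self.abundance, dtype=float)
        if ab.shape != (len(self.samples), len(self.bin_centers)):
            raise ValueError("abundance matrix shape does not match samples x bins")
        object.__setattr__(self, "abundance", ab)
        row_sums = ab.sum(axis=1)
        nonzero = row_sums > 0
        if not np.allclose(row_sums[nonzero], 1.0, atol=1e-9):
            raise ValueError("non-empty abundance rows must sum to 1")

    @property
    def presence(self) -> np.ndarray:
        return self.abundance > 0

    def bands(self, sample: str) -> frozenset[int]:
        """Indices of bins present in a sample."""
        i = self.samples.index(sample)
        return frozenset(np.flatnonzero(self.presence[i]).tolist())

    def nearest_bin(self, size: float) -> int | None:
        """Index of the bin whose center is within tolerance of ``size``."""
        if not self.bin_centers:
            return None
        centers = np.asarray(self.bin_centers)
        idx = int(np.argmin(np.abs(centers - size)))
        lo, hi = sorted((centers[idx], size))
        return idx if hi <= lo * (1.0 + self.tolerance) else None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.abundance,
            index=pd.Index(self.samples, name="sample"),
            columns=[f"{c:.3f}" for c in self.bin_centers],
        )


def _platform_from_path(path: Path) -> tuple[Platform, str] | None:
    m = _FILENAME_RE.search(path.name)
    if not m:
        return None
    return Platform(m.group(1)), m.group(2)


def read_peak_tables(paths: Iterable[str | Path]) -> list[Fingerprint]:
    """Parse delimited peak tables into one Fingerprint per (sample, platform).

    Malformed rows (negative fluorescence, non-positive size, unknown
    platform code) raise ``ValueError`` naming the file and row; a file that
    is empty apart from the header yields an empty Fingerprint when its name
    follows the ``peaks_<platform>_<sample>`` convention.
    """
    fingerprints: dict[tuple[str, Platform], list[PeakRecord]] = {}
    order: list[tuple[str, Platform]] = []
    for path in paths:
        path = Path(path)
        df = pd.read_csv(path)
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"{path}: missing required columns {missing}")
        if df.empty:
            hinted = _platform_from_path(path)
            if hinted is not None:
                platform, sample = hinted
                key = (sample, platform)
                if key not in fingerprints:
                    fingerprints[key] = []
                    order.append(key)
            continue
        for row_no, row in enumerate(df.itertuples(index=False), start=2):
            try:
                platform = Platform.parse(row.platform)
                peak = PeakRecord(
                    size=float(row.size_bp),
                    height=float(row.height),
                    area=float(row.area),
                    is_standard=bool(row.is_standard),
                )
            except ValueError as exc:
                raise ValueError(f"{path}: row {row_no}: {exc}") from None
            key = (str(row.sample), platform)
            if key not in fingerprints:
                fingerprints[key] = []
                order.append(key)
            fingerprints[key].append(peak)
    return [
        Fingerprint(sample_label=sample, platform=platform, peaks=tuple(fingerprints[(sample, platform)]))
        for sample, platform in order
    ]


def calibrate_sizes(fingerprint: Fingerprint, standard_sizes: Sequence[float]) -> Fingerprint:
    """Remap peak sizes against the fingerprint's internal size standards.

    The observed positions of the flagged standards are mapped onto their
    known ``standard_sizes`` by piecewise-linear interpolation, with linear
    extrapolation beyond the outermost standards.  Standards are removed
    from the output; peak order is preserved (the map is strictly
    increasing).
    """
    standards = fingerprint.standards
    if len(standards) < 2:
        raise ValueError(
            f"{fingerprint.sample_label}: calibration needs >= 2 internal standards, "
            f"found {len(standards)}"
        )
    truth = np.asarray(standard_sizes, dtype=float)
    if len(truth) != len(standards):
        raise ValueError(
            f"{fingerprint.sample_label}: {len(standards)} observed standards but "
            f"{len(truth)} known sizes"
        )
    if np.any(np.diff(truth) <= 0):
        raise ValueError("standard_sizes must be strictly increasing")
    observed = np.asarray([s.size for s in standards], dtype=float)
    if np.any(np.diff(observed) <= 0):
        raise ValueError(
            f"{fingerprint.sample_label}: non-monotone standard observations"
        )

    def remap(x: float) -> float:
        if x <= observed[0]:
            slope = (truth[1] - truth[0]) / (observed[1] - observed[0])
            return float(truth[0] + slope * (x - observed[0]))
        if x >= observed[-1]:
            slope = (truth[-1] - truth[-2]) / (observed[-1] - observed[-2])
            return float(truth[-1] + slope * (x - observed[-1]))
        return float(np.interp(x, observed, truth))

    new_peaks = [
        PeakRecord(size=remap(p.size), height=p.height, area=p.area)
        for p in fingerprint.sample_peaks
    ]
    return fingerprint.with_peaks(new_peaks)


def filter_peaks(
    fingerprint: Fingerprint,
    platform_model: PlatformModel,
    window: SizeWindow | None = None,
) -> Fingerprint:
    """Apply the detection threshold and the spacer analysis window.

    A peak is retained iff its height is strictly greater than the
    platform's effective threshold (baseline + 20 for the microfluidics
    chip, absolute 200 for the capillary analyzer, the configured
    densitometric cut-off for gels) and its size lies inside the window.
    Internal standards are never retained.
    """
    window = window or SizeWindow()
    threshold = platform_model.effective_threshold
    kept = [
        p
        for p in fingerprint.sample_peaks
        if p.height > threshold and window.contains(p.size)
    ]
    return fingerprint.with_peaks(kept)


def optimal_partition(sizes: Sequence[float], tolerance: float = 0.05) -> list[tuple[int, int]]:
    """Optimal binning of sorted sizes into tolerance-capped groups.

    Returns half-open index ranges ``(start, end)`` over the size-sorted
    input such that within each group ``max <= min * (1 + tolerance)``,
    minimising first the number of groups and then the summed within-group
    spread (bp).  When several partitions tie, boundary peaks join the lower
    group.  Exact dynamic program; optimal partitions of sorted sizes are
    contiguous because validity depends only on a group's extremes.
    """
    s = sorted(float(x) for x in sizes)
    n = len(s)
    if n == 0:
        return []
    if any(x <= 0 for x in s):
        raise ValueError("sizes must be positive")
    INF = (n + 1, float("inf"))
    # best[j] = (bins, spread) for the first j peaks; choice[j] = start of last bin
    best: list[tuple[int, float]] = [INF] * (n + 1)
    choice = [-1] * (n + 1)
    best[0] = (0, 0.0)
    for j in range(1, n + 1):
        for i in range(j - 1, -1, -1):
            if s[j - 1] > s[i] * (1.0 + tolerance):
                break  # bins are contiguous; widening further only worsens
            cand = (best[i][0] + 1, best[i][1] + (s[j - 1] - s[i]))
            # strict < with i descending keeps the largest i on ties, so the
            # boundary peak stays in the lower bin
            if cand < best[j]:
                best[j] = cand
                choice[j] = i
    if choice[n] < 0:
        raise ValueError("no valid partition (internal error)")
    bounds: list[tuple[int, int]] = []
    j = n
    while j > 0:
        i = choice[j]
        bounds.append((i, j))
        j = i
    return bounds[::-1]


def bin_peaks(
    fingerprints: Sequence[Fingerprint],
    tolerance: float = 0.05,
) -> BinTable:
    """Group peak sizes across samples into shared ±tolerance bins.

    All fingerprints must come from one platform (profiles from different
    platforms are compared only through derived statistics, never co-binned).
    Bin centers are the area-weighted mean sizes of their members; within a
    sample, areas of multiple peaks falling into one bin are summed, and
    relative abundance is each bin's area over the sample's total retained
    area.
    """
    if not fingerprints:
        raise ValueError("no fingerprints to bin")
    platforms = {fp.platform for fp in fingerprints}
    if len(platforms) > 1:
        raise ValueError(
            f"refusing to co-bin fingerprints from multiple platforms: "
            f"{sorted(p.value for p in platforms)}"
        )
    labels = [fp.sample_label for fp in fingerprints]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate sample labels")

    entries: list[tuple[float, int, float]] = []  # (size, sample index, area)
    for si, fp in enumerate(fingerprints):
        for p in fp.sample_peaks:
            entries.append((p.size, si, p.area))
    entries.sort(key=lambda e: e[0])
    sizes = [e[0] for e in entries]
    bounds = optimal_partition(sizes, tolerance)

    n_samples = len(fingerprints)
    centers: list[float] = []
    areas = np.zeros((n_samples, len(bounds)))
    for b, (i, j) in enumerate(bounds):
        members = entries[i:j]
        w = sum(a for _, _, a in members)
        if w > 0:
            centers.append(sum(sz * a for sz, _, a in members) / w)
        else:
            centers.append(float(np.mean([sz for sz, _, _ in members])))
        for _, si, a in members:
            areas[si, b] += a

    totals = areas.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        abundance = np.where(totals > 0, areas / np.where(totals > 0, totals, 1.0), 0.0)
    return BinTable(
        bin_centers=tuple(centers),
        samples=tuple(labels),
        abundance=abundance,
        tolerance=tolerance,
        platform=next(iter(platforms)),
    )


def band_richness(bin_table: BinTable) -> dict[str, int]:
    """Number of bins present per sample."""
    counts = bin_table.presence.sum(axis=1)
    return {s: int(c) for s, c in zip(bin_table.samples, counts)}


def write_bin_table(bin_table: BinTable, path: str | Path) -> None:
    """Serialize a BinTable as delimited text with a metadata comment line."""
    path = Path(path)
    platform = bin_table.platform.value if bin_table.platform else ""
    with open(path, "w") as fh:
        fh.write(f"# tolerance={bin_table.tolerance} platform={platform}\n")
        bin_table.to_frame().to_csv(fh, float_format="%.10f")


def read_bin_table(path: str | Path) -> BinTable:
    path = Path(path)
    text = path.read_text()
    tolerance, platform = 0.05, None
    lines = text.splitlines(keepends=True)
    if lines and lines[0].startswith("#"):
        m = re.search(r"tolerance=([\d.eE+-]+)", lines[0])
        if m:
            tolerance = float(m.group(1))
        m = re.search(r"platform=(\w+)", lines[0])
        if m:
            platform = Platform(m.group(1))
        text = "".join(lines[1:])
    df = pd.read_csv(io.StringIO(text), index_col=0)
    return BinTable(
        bin_centers=tuple(float(c) for c in df.columns),
        samples=tuple(str(s) for s in df.index),
        abundance=df.to_numpy(dtype=float),
        tolerance=tolerance,
        platform=platform,
    )
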