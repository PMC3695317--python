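"""Core data model for RISA/ARISA fingerprint analysis.

A *fingerprint* is the set of DNA fragments (bands on a gel, peaks in an
electropherogram) detected for one sample on one platform.  Three platform
styles are supported: polyacrylamide gel densitometry (``GEL``), a
microfluidics chip instrument (``MF``) and a capillary genetic analyzer
(``GA``).  They differ in detection threshold conventions, reportable size
range and internal size standards, which :class:`PlatformModel` captures.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Sequence


class Platform(enum.Enum):
    """Fragment-analysis platform style."""

    GEL = "gel"
    MF = "mf"
    GA = "ga"

    @classmethod
    def parse(cls, value: "str | Platform") -> "Platform":
        if isinstance(value, Platform):
            return value
        try:
            return cls(str(value).strip().lower())
        except ValueError:
            raise ValueError(f"unknown platform code: {value!r}") from None


@dataclass(frozen=True)
class PeakRecord:
    """One detected fragment.

    Parameters
    ----------
    size:
        Fragment size in bp (possibly uncalibrated migration-scale units
        before :func:`arisa.peaks.calibrate_sizes`).
    height:
        Peak height in fluorescence units (densitometric height for gels).
    area:
        Peak area in fluorescence units.
    is_standard:
        True for internal size-standard fragments co-run with the sample.
    """

    size: float
    height: float
    area: float
    is_standard: bool = False

    def __post_init__(self) -> None:
        if self.height < 0 or self.area < 0:
            raise ValueError(
                f"negative fluorescence (height={self.height}, area={self.area})"
            )
        if self.size <= 0:
            raise ValueError(f"non-positive fragment size: {self.size}")


@dataclass(frozen=True)
class Fingerprint:
    """All peaks detected for one sample on one platform, sorted by size."""

    sample_label: str
    platform: Platform
    peaks: tuple[PeakRecord, ...] = ()

    def __post_init__(self) -> None:
        ordered = tuple(sorted(self.peaks, key=lambda p: p.size))
        object.__setattr__(self, "peaks", ordered)

    @property
    def sample_peaks(self) -> tuple[PeakRecord, ...]:
        """Peaks excluding internal size standards."""
        return tuple(p for p in self.peaks if not p.is_standard)

    @property
    def standards(self) -> tuple[PeakRecord, ...]:
        return tuple(p for p in self.peaks if p.is_standard)

    def with_peaks(self, peaks: Sequence[PeakRecord]) -> "Fingerprint":
        return replace(self, peaks=tuple(peaks))


@dataclass(frozen=True)
class PlatformModel:
    """Detection behaviour of one platform.

    ``detection_threshold`` is interpreted relative to ``baseline`` for the
    microfluidics platform (a peak is kept when its height is strictly
    greater than ``baseline + detection_threshold``) and as an absolute
    fluorescence cut-off for the capillary analyzer and gel densitometry.
    """

    platform: Platform
    size_jitter_sd: float = 0.0
    fluorescence_cv: float = 0.0
    baseline: float = 0.0
    detection_threshold: float = 0.0
    reportable_range: tuple[float, float] = (1.0, 5000.0)
    internal_standards: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        low, high = self.reportable_range
        if not low < high:
            raise ValueError(f"reportable_range must satisfy low < high, got {low}, {high}")
        if self.size_jitter_sd < 0:
            raise ValueError("size_jitter_sd must be >= 0")
        if self.detection_threshold < 0:
            raise ValueError("detection_threshold must be >= 0")

    @property
    def effective_threshold(self) -> float:
        """Height a peak must strictly exceed to be retained."""
        if self.platform is Platform.MF:
            return self.baseline + self.detection_threshold
        return self.detection_threshold


# Flank lengths co-amplified with the intergenic spacer by the methanogen
# primer pair: 202 bp of the 16S and 170 bp of the 23S rRNA gene.
DEFAULT_FLANK_16S = 202
DEFAULT_FLANK_23S = 170
MIN_RIS_AMPLICON = DEFAULT_FLANK_16S + DEFAULT_FLANK_23S  # 372 bp


@dataclass(frozen=True)
class SizeWindow:
    """Analysis window for spacer-bearing amplicons.

    Amplicons shorter than ``min_ris_amplicon`` (the two rRNA flanks alone)
    cannot contain a spacer; the default analysis window of 400–1000 bp sits
    above that theoretical floor.
    """

    low: float = 400.0
    high: float = 1000.0
    min_ris_amplicon: float = float(MIN_RIS_AMPLICON)

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise ValueError("window requires low < high")
        if self.low < self.min_ris_amplicon:
            raise ValueError(
                f"window low {self.low} below minimum spacer-bearing amplicon "
                f"{self.min_ris_amplicon}"
            )

    def contains(self, size: float) -> bool:
        return self.low <= size <= self.high


def default_platform_models() -> dict[Platform, PlatformModel]:
    """Default platform behaviour used by the synthetic study design.

    The microfluidics chip carries 15 and 1,500 bp internal markers and a
    manual threshold of 20 units above baseline; the capillary analyzer
    reports 100–1,000 bp against a ladder with an absolute 200-unit
    threshold; gel densitometry has no internal standards and a configurable
    (default 120-unit) densitometric cut-off.
    """
    return {
        Platform.GEL: PlatformModel(
            platform=Platform.GEL,
            size_jitter_sd=3.0,
            fluorescence_cv=0.15,
            baseline=0.0,
            detection_threshold=120.0,
            reportable_range=(100.0, 2000.0),
            internal_standards=(),
        ),
        Platform.MF: PlatformModel(
            platform=Platform.MF,
            size_jitter_sd=1.5,
            fluorescence_cv=0.10,
            baseline=10.0,
            detection_threshold=20.0,
            reportable_range=(15.0, 1500.0),
            internal_standards=(15.0, 1500.0),
        ),
        Platform.GA: PlatformModel(
            platform=Platform.GA,
            size_jitter_sd=0.5,
            fluorescence_cv=0.05,
            baseline=0.0,
            detection_threshold=200.0,
            reportable_range=(100.0, 1000.0),
            internal_standards=(100.0, 200.0, 300.0, 400.0, 500.0, 600.0, 700.0, 800.0, 900.0, 1000.0),
        ),
    }
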