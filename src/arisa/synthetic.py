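"""Synthetic communities and their rendering as per-platform peak tables.

The generator emulates a six-timepoint anaerobic-digester monitoring design:
an inoculum, a near-identical sample 24 h later, and a compositional shift
from day 10 onward after which a two-operon *Methanosarcina*-like taxon
(spacer amplicons of 652 and 590 bp) dominates and biogas production jumps
from near zero to steady-state levels.  Rendering turns a ground-truth
community into the noisy peak table a gel densitometer, a microfluidics chip
or a capillary analyzer would report, so every downstream stage of the
pipeline has a parameter-recovery test with a known truth.

Noise model: Gaussian jitter on fragment size, multiplicative log-normal
noise (given as a coefficient of variation) on fluorescence; both default to
platform-specific values and can be set to zero, in which case rendered
sizes and areas are exact functions of the truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .models import (
    DEFAULT_FLANK_16S,
    DEFAULT_FLANK_23S,
    Fingerprint,
    PeakRecord,
    Platform,
    PlatformModel,
    default_platform_models,
)

__all__ = [
    "OperonTemplate",
    "CommunityState",
    "ScenarioConfig",
    "default_templates",
    "default_scenario",
    "simulate_timeseries",
    "render_fingerprint",
    "process_parameters",
    "write_fixture_set",
    "DEFAULT_TOTAL_SIGNAL",
    "DEFAULT_HEIGHT_FACTOR",
]


@dataclass(frozen=True)
class OperonTemplate:
    """One rRNA operon of a taxon: spacer length plus the amplified flanks.

    A taxon may own several templates (multi-operon genomes produce several
    bands from one organism); ``operon_weight`` scales that operon's relative
    copy contribution to the taxon's signal.
    """

    taxon_label: str
    ris_length: int
    flank_16s: int = DEFAULT_FLANK_16S
    flank_23s: int = DEFAULT_FLANK_23S
    operon_weight: float = 1.0

    def __post_init__(self) -> None:
        if self.ris_length <= 0:
            raise ValueError("ris_length must be positive")
        if self.operon_weight <= 0:
            raise ValueError("operon_weight must be positive")

    @property
    def amplicon_length(self) -> int:
        return self.ris_length + self.flank_16s + self.flank_23s


@dataclass(frozen=True)
class CommunityState:
    """Relative taxon composition of one sample; abundances sum to one."""

    sample_label: str
    abundances: Mapping[str, float]

    def __post_init__(self) -> None:
        clean = {t: float(a) for t, a in self.abundances.items() if a > 0}
        if not clean:
            raise ValueError(f"community {self.sample_label!r} has no positive abundance")
        if any(a < 0 for a in self.abundances.values()):
            raise ValueError("negative abundance")
        total = sum(clean.values())
        object.__setattr__(
            self, "abundances", {t: a / total for t, a in sorted(clean.items())}
        )


@dataclass(frozen=True)
class ScenarioConfig:
    """Time-series design: which samples exist and how the community shifts.

    ``turnover`` is the fraction of the community replaced by the post-shift
    target composition from the shift sample onward (0 = no shift at all,
    1 = complete replacement).  Biogas production is coupled to the
    abundance of ``coupled_taxon`` as ``intercept + slope * abundance`` plus
    Gaussian noise, and methane is a fixed fraction of biogas; the inoculum
    carries no production values.
    """

    sample_labels: tuple[str, ...] = (
        "inoculum",
        "day1",
        "day10",
        "day22",
        "day30",
        "day43",
    )
    shift_index: int = 2  # first post-shift sample (day 10)
    pre_community: Mapping[str, float] = field(
        default_factory=lambda: {
            "Methanosaeta_like": 0.33,
            "Methanobacterium_like": 0.27,
            "Methanospirillum_like": 0.18,
            "Methanolinea_like": 0.13,
            "rare_A": 0.045,
            "rare_B": 0.020,
            "rare_C": 0.012,
            "rare_D": 0.008,
            "rare_E": 0.005,
        }
    )
    post_community: Mapping[str, float] = field(
        default_factory=lambda: {
            "Methanosarcina_like": 0.52,
            "Methanoculleus_like": 0.22,
            "Methanolinea_like": 0.18,
            "rare_A": 0.035,
            "rare_B": 0.020,
            "rare_C": 0.012,
            "rare_D": 0.008,
            "rare_E": 0.005,
        }
    )
    turnover: float = 0.85
    state_noise_cv: float = 0.05
    coupled_taxon: str = "Methanosarcina_like"
    biogas_intercept: float = 0.15
    biogas_slope: float = 17.5
    biogas_noise_sd: float = 0.15
    methane_fraction: float = 0.63
    methane_noise_sd: float = 0.10
    samples_without_production: tuple[str, ...] = ("inoculum",)

    def __post_init__(self) -> None:
        if not 0.0 <= self.turnover <= 1.0:
            raise ValueError("turnover fraction must lie in [0, 1]")
        if not self.sample_labels:
            raise ValueError("scenario names no samples")


def default_templates() -> list[OperonTemplate]:
    """Default taxon/operon library.

    All amplicon lengths are mutually more than 5 % apart so the default
    scenario produces unambiguous bins; the post-shift dominant carries two
    operons (spacers 280 and 218 bp -> amplicons 652 and 590 bp), the
    multi-band single-organism pattern seen for dominant digester
    methanogens.
    """
    return [
        OperonTemplate("Methanosarcina_like", ris_length=280, operon_weight=1.0),
        OperonTemplate("Methanosarcina_like", ris_length=218, operon_weight=0.8),
        OperonTemplate("Methanoculleus_like", ris_length=68),
        OperonTemplate("Methanospirillum_like", ris_length=133),
        OperonTemplate("Methanosaeta_like", ris_length=388),
        OperonTemplate("Methanobacterium_like", ris_length=458),
        OperonTemplate("Methanolinea_like", ris_length=538),
        OperonTemplate("rare_A", ris_length=43),
        OperonTemplate("rare_B", ris_length=108),
        OperonTemplate("rare_C", ris_length=183),
        OperonTemplate("rare_D", ris_length=318),
        OperonTemplate("rare_E", ris_length=588),
    ]


def default_scenario() -> ScenarioConfig:
    return ScenarioConfig()


# Total injected fluorescence per platform; together with the detection
# thresholds these set each platform's effective abundance cut-off
# (capillary ~0.4 %, gel ~6 %, chip ~3 %), which reproduces the observed
# richness ordering capillary > chip/gel.
DEFAULT_TOTAL_SIGNAL: dict[Platform, float] = {
    Platform.GEL: 4_000.0,
    Platform.MF: 2_000.0,
    Platform.GA: 100_000.0,
}

# Rendered peak height as a fraction of its area (sharp, symmetric peaks).
DEFAULT_HEIGHT_FACTOR = 0.5


def _rng(seed: int, *subkeys: int) -> np.random.Generator:
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, *subkeys])


def _perturb(abundances: Mapping[str, float], cv: float, rng: np.random.Generator) -> dict[str, float]:
    if cv <= 0:
        return dict(abundances)
    sigma = float(np.sqrt(np.log1p(cv * cv)))
    taxa = sorted(abundances)
    factors = np.exp(rng.normal(-sigma * sigma / 2.0, sigma, size=len(taxa)))
    return {t: abundances[t] * f for t, f in zip(taxa, factors)}


def simulate_timeseries(
    templates: Sequence[OperonTemplate],
    scenario: ScenarioConfig | None = None,
    seed: int = 0,
) -> list[CommunityState]:
    """Generate one CommunityState per scenario sample.

    Pre-shift samples are small-noise replicates of the pre-shift
    composition; from ``shift_index`` onward each sample is the
    ``turnover``-weighted mixture of pre- and post-shift compositions plus
    small noise, so consecutive post-shift samples differ only by noise.
    Deterministic for a given seed.
    """
    scenario = scenario or default_scenario()
    if not templates:
        raise ValueError("empty template list")
    known = {t.taxon_label for t in templates}
    used = set(scenario.pre_community) | set(scenario.post_community)
    missing = used - known
    if missing:
        raise ValueError(f"scenario taxa without operon templates: {sorted(missing)}")

    pre = dict(scenario.pre_community)
    post = dict(scenario.post_community)
    taxa = sorted(set(pre) | set(post))
    states: list[CommunityState] = []
    for i, label in enumerate(scenario.sample_labels):
        if i < scenario.shift_index:
            mix = {t: pre.get(t, 0.0) for t in taxa}
        else:
            mix = {
                t: (1.0 - scenario.turnover) * pre.get(t, 0.0)
                + scenario.turnover * post.get(t, 0.0)
                for t in taxa
            }
        # the inoculum is the reference composition itself; later samples add noise
        if i > 0:
            mix = _perturb(mix, scenario.state_noise_cv, _rng(seed, 101, i))
        states.append(CommunityState(label, {t: a for t, a in mix.items() if a > 0}))
    return states


def render_fingerprint(
    state: CommunityState,
    templates: Sequence[OperonTemplate],
    platform: PlatformModel,
    seed: int = 0,
    total_signal: float | None = None,
    height_factor: float = DEFAULT_HEIGHT_FACTOR,
) -> Fingerprint:
    """Render one community as the peak table a platform would report.

    One candidate peak per (taxon, operon) pair with positive abundance:
    size = amplicon length + Gaussian jitter; area proportional to
    abundance x operon weight with unit-mean log-normal noise; peaks whose
    height does not strictly exceed the platform's effective threshold, or
    whose size falls outside the reportable range, are dropped.  Internal
    size standards are appended as flagged records.
    """
    by_taxon: dict[str, list[OperonTemplate]] = {}
    for t in templates:
        by_taxon.setdefault(t.taxon_label, []).append(t)
    for taxon in state.abundances:
        if taxon not in by_taxon:
            raise ValueError(f"taxon {taxon!r} has no operon template")

    if total_signal is None:
        total_signal = DEFAULT_TOTAL_SIGNAL[platform.platform]
    rng = _rng(seed, 202, list(Platform).index(platform.platform))

    signals: list[tuple[OperonTemplate, float]] = []
    for taxon, abundance in state.abundances.items():
        for tpl in by_taxon[taxon]:
            signals.append((tpl, abundance * tpl.operon_weight))
    norm = sum(s for _, s in signals)

    sigma = float(np.sqrt(np.log1p(platform.fluorescence_cv**2)))
    peaks: list[PeakRecord] = []
    for tpl, signal in signals:
        mean_area = total_signal * signal / norm
        if platform.fluorescence_cv > 0:
            area = mean_area * float(np.exp(rng.normal(-sigma * sigma / 2.0, sigma)))
        else:
            area = mean_area
        size = float(tpl.amplicon_length)
        if platform.size_jitter_sd > 0:
            size += float(rng.normal(0.0, platform.size_jitter_sd))
        height = area * height_factor
        low, high = platform.reportable_range
        if height > platform.effective_threshold and low <= size <= high:
            peaks.append(PeakRecord(size=size, height=height, area=area))

    standard_height = max(10.0 * platform.effective_threshold, 1_000.0)
    for std in platform.internal_standards:
        peaks.append(
            PeakRecord(size=float(std), height=standard_height, area=2.0 * standard_height, is_standard=True)
        )
    return Fingerprint(sample_label=state.sample_label, platform=platform.platform, peaks=tuple(peaks))


def process_parameters(
    states: Sequence[CommunityState],
    scenario: ScenarioConfig | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-sample biogas/methane volumes coupled to the dominant's abundance.

    Biogas (L/day) rises linearly with the coupled taxon's abundance, so
    post-shift samples show the characteristic jump from near-zero start-up
    production to steady state.  Samples listed in
    ``samples_without_production`` (the inoculum) get missing values.
    """
    scenario = scenario or default_scenario()
    rng = _rng(seed, 303)
    rows = []
    for state in states:
        if state.sample_label in scenario.samples_without_production:
            rows.append({"sample": state.sample_label, "biogas_l_day": np.nan, "methane_l_day": np.nan})
            continue
        a = state.abundances.get(scenario.coupled_taxon, 0.0)
        biogas = scenario.biogas_intercept + scenario.biogas_slope * a
        biogas += float(rng.normal(0.0, scenario.biogas_noise_sd))
        biogas = max(biogas, 0.0)
        methane = scenario.methane_fraction * biogas + float(rng.normal(0.0, scenario.methane_noise_sd))
        methane = min(max(methane, 0.0), biogas)
        rows.append({"sample": state.sample_label, "biogas_l_day": biogas, "methane_l_day": methane})
    return pd.DataFrame(rows)


def write_fixture_set(
    states: Sequence[CommunityState],
    platforms: Iterable[PlatformModel] | None = None,
    out_dir: str | Path = ".",
    seed: int = 0,
    templates: Sequence[OperonTemplate] | None = None,
    scenario: ScenarioConfig | None = None,
) -> dict:
    """Write the full fixture set and return a file manifest.

    One delimited peak table per sample x platform, a truth table of
    community compositions, the operon template table and the
    process-parameter table.  Byte-identical for identical inputs and seed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    templates = list(templates) if templates is not None else default_templates()
    scenario = scenario or default_scenario()
    platform_list = list(platforms) if platforms is not None else list(default_platform_models().values())

    manifest: dict = {"peak_tables": [], "truth": None, "templates": None, "parameters": None}
    for p_idx, platform in enumerate(platform_list):
        for s_idx, state in enumerate(states):
            fp = render_fingerprint(
                state, templates, platform, seed=_child_seed(seed, p_idx, s_idx)
            )
            df = pd.DataFrame(
                {
                    "sample": [fp.sample_label] * len(fp.peaks),
                    "platform": [fp.platform.value] * len(fp.peaks),
                    "size_bp": [p.size for p in fp.peaks],
                    "height": [p.height for p in fp.peaks],
                    "area": [p.area for p in fp.peaks],
                    "is_standard": [p.is_standard for p in fp.peaks],
                }
            )
            path = out / f"peaks_{platform.platform.value}_{state.sample_label}.csv"
            df.to_csv(path, index=False, float_format="%.6f")
            manifest["peak_tables"].append(str(path))

    truth = pd.DataFrame(
        [
            {"sample": s.sample_label, "taxon": t, "abundance": a}
            for s in states
            for t, a in s.abundances.items()
        ]
    )
    truth_path = out / "truth.csv"
    truth.to_csv(truth_path, index=False, float_format="%.10f")
    manifest["truth"] = str(truth_path)

    tpl = pd.DataFrame(
        [
            {
                "taxon": t.taxon_label,
                "ris_length": t.ris_length,
                "flank_16s": t.flank_16s,
                "flank_23s": t.flank_23s,
                "operon_weight": t.operon_weight,
            }
            for t in templates
        ]
    )
    tpl_path = out / "templates.csv"
    tpl.to_csv(tpl_path, index=False, float_format="%.6f")
    manifest["templates"] = str(tpl_path)

    params = process_parameters(states, scenario, seed=seed)
    params_path = out / "parameters.csv"
    params.to_csv(params_path, index=False, float_format="%.6f")
    manifest["parameters"] = str(params_path)

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _child_seed(seed: int, p_idx: int, s_idx: int) -> int:
    # stable per-file sub-seed, kept well below 2**31
    return (int(seed) * 1_000 + p_idx * 100 + s_idx) & 0x7FFFFFFF
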