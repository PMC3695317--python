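"""Shared fixtures: the default synthetic study design, rendered per platform."""

from __future__ import annotations

import numpy as np
import pytest

from arisa import (
    Platform,
    bin_peaks,
    calibrate_sizes,
    default_platform_models,
    default_scenario,
    default_templates,
    filter_peaks,
    render_fingerprint,
    simulate_timeseries,
    write_fixture_set,
)

SEED = 1


@pytest.fixture(scope="session")
def templates():
    return default_templates()


@pytest.fixture(scope="session")
def scenario():
    return default_scenario()


@pytest.fixture(scope="session")
def states(templates, scenario):
    return simulate_timeseries(templates, scenario, seed=SEED)


@pytest.fixture(scope="session")
def platform_models():
    return default_platform_models()


def run_pipeline(states, templates, model, seed=SEED):
    """Render, calibrate, filter and bin one platform's fingerprints."""
    fps = []
    for i, st in enumerate(states):
        fp = render_fingerprint(st, templates, model, seed=1000 * seed + i)
        if model.internal_standards:
            fp = calibrate_sizes(fp, model.internal_standards)
        fps.append(filter_peaks(fp, model))
    return fps, bin_peaks(fps)


@pytest.fixture(scope="session")
def ga_pipeline(states, templates, platform_models):
    return run_pipeline(states, templates, platform_models[Platform.GA])


@pytest.fixture(scope="session")
def mf_pipeline(states, templates, platform_models):
    return run_pipeline(states, templates, platform_models[Platform.MF])


@pytest.fixture(scope="session")
def gel_pipeline(states, templates, platform_models):
    return run_pipeline(states, templates, platform_models[Platform.GEL])


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory, states, templates, scenario):
    out = tmp_path_factory.mktemp("fixtures")
    write_fixture_set(states, out_dir=out, seed=SEED, templates=templates, scenario=scenario)
    return out


# ---- independent oracles -------------------------------------------------

def brute_force_binning(sizes, tolerance=0.05):
    """Exhaustive search over contiguous partitions of the sorted sizes.

    Returns the optimal (n_bins, total_spread) under the validity rule
    max <= min * (1 + tolerance) per bin.  Independent of the package's
    dynamic program.
    """
    s = sorted(sizes)
    n = len(s)
    best = (n + 1, float("inf"))
    for mask in range(1 << max(n - 1, 0)):
        bounds = [0] + [i + 1 for i in range(n - 1) if mask & (1 << i)] + [n]
        ok = True
        spread = 0.0
        for a, b in zip(bounds, bounds[1:]):
            if s[b - 1] > s[a] * (1 + tolerance):
                ok = False
                break
            spread += s[b - 1] - s[a]
        if ok:
            cand = (len(bounds) - 1, spread)
            if cand < best:
                best = cand
    return best


def all_set_partitions(items):
    """Every partition of a small set (for validating the contiguity argument)."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in all_set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1 :]
        yield [[first]] + part


def make_operon(ris_length, rng, fwd_variant, rev_variant, flank_left=400, flank_right=300):
    """Random template sequence with a planted convergent primer-site pair.

    The planted product spans ris_length + 372 bp: the forward site, the
    interior (spacer plus the remaining rRNA flanks), then the reverse
    complement of the reverse-primer variant.
    """
    comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
    rc = "".join(comp[c] for c in reversed(rev_variant))
    amplicon = ris_length + 372
    interior = amplicon - len(fwd_variant) - len(rev_variant)
    assert interior >= 0
    def rand(n):
        return "".join(rng.choice(list("ACGT"), size=n))
    return rand(flank_left) + fwd_variant + rand(interior) + rc + rand(flank_right)
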