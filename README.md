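# arisa

Analysis toolkit for **ribosomal intergenic spacer analysis (RISA/ARISA)**
fingerprints of methanogenic *Archaea* communities — the kind of monitoring
data produced while tracking an anaerobic digester's microbial community
over a start-up period.

RISA profiles a community by amplifying the variable-length spacer between
the 16S and 23S rRNA genes: each distinct fragment length is a putative
taxon signature. The same community can be profiled on a polyacrylamide gel
(densitometric band tables), a microfluidics chip, or a capillary genetic
analyzer; the platforms differ in detection thresholds, size calibration and
resolution. This package takes the per-platform *peak tables* (fragment
size, height, area) and carries them through the standard analysis:

- **Peak processing** — size calibration against internal standards
  (piecewise-linear), platform detection thresholds (strictly above
  baseline + 20 fluorescence units for the chip, above an absolute 200 for
  the capillary analyzer), the 400–1000 bp spacer analysis window, and
  grouping of fragment sizes across samples that agree within **±5 %** into
  shared bins with per-sample relative abundance
  `p_i = area_i / Σ area` (`arisa.peaks`).
- **Diversity** — Shannon index `H' = −Σ (n_i/N) log(n_i/N)` on peak
  heights (`arisa.diversity`).
- **Similarity and clustering** — presence/absence Dice coefficient
  `Dc = 2j/(a+b)`, UPGMA dendrograms on `1 − Dc`, and clade supports from a
  bin-column bootstrap (`arisa.clustering`).
- **Process correlation** — Pearson correlation (two-sided t test, n−2 df,
  significance at P < 0.05) between chosen bins' relative abundances and
  reactor performance such as daily biogas/methane volumes
  (`arisa.correlation`).
- **In-silico PCR** — IUPAC-degenerate primer matching over rRNA-operon
  sequences with the methanogen-specific 16S/23S primer pair. Every product
  carries 202 bp of 16S and 170 bp of 23S sequence, so
  `spacer = amplicon − 372 bp`; observed bins are mapped back to candidate
  source taxa, including multi-operon organisms that legitimately claim
  several bins (`arisa.ispcr`).
- **Synthetic study designs** — a generator that emulates a six-timepoint
  digester experiment (inoculum; days 1, 10, 22, 30, 43; community shift at
  day 10; a two-operon dominant at 652 + 590 bp coupled to biogas
  production) and renders ground-truth communities as noisy per-platform
  peak tables, so every stage has a parameter-recovery test
  (`arisa.synthetic`).

## Worked example

```python
import numpy as np
from arisa import (
    PAPER_PRIMERS, Platform, bin_peaks, calibrate_sizes, correlate_bins,
    default_platform_models, default_scenario, default_templates,
    dice_coefficient, expand_degeneracies, filter_peaks, bootstrap_supports,
    process_parameters, render_fingerprint, simulate_timeseries,
)

templates, scenario = default_templates(), default_scenario()
states = simulate_timeseries(templates, scenario, seed=1)
ga = default_platform_models()[Platform.GA]

fps = []
for i, state in enumerate(states):
    fp = render_fingerprint(state, templates, ga, seed=1000 + i)
    fp = calibrate_sizes(fp, ga.internal_standards)
    fps.append(filter_peaks(fp, ga))
table = bin_peaks(fps)

print(dice_coefficient(table.bands("inoculum"), table.bands("day1")))   # 1.0
print(dice_coefficient(table.bands("inoculum"), table.bands("day10")))  # 0.8

tree = bootstrap_supports(table, n_reps=200, seed=7)
print(tree.newick())
# ((day1:0,inoculum:0)0.97:0.0929,(((day10:0,day22:0)0.995:0,day43:0)0.67:0.0217,
#  day30:0.0217)0.795:0.0711)1;

params = process_parameters(states, scenario, seed=1)
for r in correlate_bins(table, params, [652.0, 590.0]):
    print(r.bin_id, r.parameter, round(r.Pc, 3), round(r.p_value, 4))
# 652bp biogas_l_day 0.998 0.0002   <- dominant's first operon vs biogas
# 652bp methane_l_day 0.994 0.0006
# 590bp biogas_l_day 0.998 0.0001
# 590bp methane_l_day 0.999 0.0
```

The Dice values say the day-1 sample is indistinguishable from the inoculum
while the day-10 sample is not — the community shift; the tree splits
{inoculum, day 1} from all later samples with ~0.97 bootstrap support; and
both fragment bins of the dominant methanogen track biogas production with
near-perfect, significant Pearson correlations (n = 5: the inoculum carries
no production data and is excluded).

Degenerate-primer arithmetic and spacer lengths:

```python
print(expand_degeneracies(PAPER_PRIMERS["16S-RIS-M"])[0])  # 2 variants
print(expand_degeneracies(PAPER_PRIMERS["23S-RIS-M"])[0])  # 192 variants
```

A predicted 652 bp amplicon implies a 280 bp spacer; 590 bp implies 218 bp;
anything at 372 bp is flank-only and carries no spacer.

## Command line

```sh
arisa simulate --seed 1 --out fixtures/
arisa process --in fixtures/ --platform ga --tolerance 0.05 --window 400:1000 --out bins.csv
arisa diversity --in fixtures/ --platform ga --out diversity.csv
arisa cluster --bins bins.csv --bootstrap 1000 --seed 42 --out tree.nwk
arisa correlate --bins bins.csv --params fixtures/parameters.csv --bins-of-interest 652,590 --out corr.csv
arisa ispcr --fasta operons.fa --fwd 16S-RIS-M --rev 23S-RIS-M --max-len 3000
```

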