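"""Genome-diversity battery on a simulated two-population cohort.

Simulates a 2-Mb diploid cohort, applies the depth and repeat-mask filters,
then computes SNV rates, windowed density, heterozygous/homozygous window
classification and runs of homozygosity for one individual.
"""

import numpy as np

from bkit.diversity import (
    MaskSet,
    classify_het_hom,
    detect_roh,
    filter_by_depth,
    filter_by_mask,
    heterozygosity_rates,
    snv_rate,
    window_density,
)
from bkit.syndata import DemographyScenario, simulate_two_pop_cohort

L = 2_000_000
scenario = DemographyScenario(
    model_id="CONST", ancestral_size=10_000, epoch_params={},
    mutation_rate=0.9e-8, rate_units="generation",
    sequence_length=L, sample_sizes=(8, 6))
cohort = simulate_two_pop_cohort(scenario, seed=1)
table = cohort.variants
print(f"simulated sites: {table.n_sites}")

table, log = filter_by_depth(table, 5, 30)
print(f"after 5x-30x depth filter: {log['kept_sites']} sites")

mask = MaskSet.from_bed({"scaf1": [(500_000, 550_000), (1_200_000, 1_230_000)]})
table, removed, pct = filter_by_mask(table, mask)
print(f"after repeat mask: {table.n_sites} sites ({pct:.0f} % retained)")

rates = snv_rate(table, L)
print("per-individual SNV rate (variants/bp):")
print(rates.round(6).to_string())

het = heterozygosity_rates(table, L)
print(f"heterozygous-site rate: {het.min():.4f}-{het.max():.4f} % of positions")

wins, summary = window_density(table.scaffold, table.pos, {"scaf1": L},
                               window=50_000)
print(f"50-kbp windows: {summary['n_windows']} covering "
      f"{100 * summary['fraction_covered']:.1f} % of the genome; "
      f"mean {wins['snv_count'].mean():.1f} SNVs/window")

ind = 0
is_het = table.is_het()[:, ind]
wins_hh, hh = classify_het_hom(table.scaffold[is_het], table.pos[is_het],
                               {"scaf1": L})
print(f"individual {table.samples[ind]}: {hh['percent_homozygous']:.0f} % of "
      f"100-kbp windows homozygous (<= 40 heterozygous SNVs)")

segs, median = detect_roh(table.scaffold, table.pos, is_het)
print(f"runs of homozygosity: {len(segs)} segments, median length "
      f"{median if segs else float('nan'):.0f} bp")
print("(in a constant-size outbred population ROH stay short; a "
      "bottlenecked cohort would show many long segments)")
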