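"""Windowed diversity and differentiation between the recipient ecotype
(TP_E) and the donor species (HS), plus the Z(FST)/log10(pi-ratio)
selection scan."""

import numpy as np

from introflow import coalsim, genotypes, popgen

model = coalsim.scenario_preset("study_pulse", phi=0.1)
ds = coalsim.simulate(model, {"HS": 4, "TP_E": 4, "TP_M": 4, "TP_W": 4, "J": 2},
                      n_loci=190, locus_length=1000, seed=2, n_contigs=19)
gm = genotypes.from_simulated(ds)

windows = genotypes.make_windows(gm.contigs, width=10_000)
stats = popgen.window_diversity(gm, populations=["TP_E", "HS"], windows=windows)
frame = popgen.window_stats_frame(stats)
print(frame[["contig", "n_sites", "pi_TP_E", "pi_HS", "dxy_TP_E|HS",
             "fst_TP_E|HS", "tajima_d_TP_E"]].head())
print(f"\nmean FST(TP_E, HS) = {frame['fst_TP_E|HS'].mean():.3f}, "
      f"mean Dxy = {frame['dxy_TP_E|HS'].mean():.3f}")
# pi/Dxy are per accessible variant site; FST is Hudson's ratio of averages

scan = popgen.selection_scan(frame["fst_TP_E|HS"], frame["pi_TP_E"],
                             frame["pi_HS"], quantile=0.95)
print(f"selection scan: {len(scan['outliers'])} windows in the top 5% of "
      f"both Z(FST) and log10(pi ratio)")

curve = popgen.ld_decay(gm, "TP_E", max_dist_bp=5000, bin_width=1000)
print(f"LD half-decay distance: {curve.half_decay_bp} bp")
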