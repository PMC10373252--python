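"""Mixed-model GWAS on the training set and panel preselection.

Runs the EMMAX-style scan on a line with 10 large QTL, then cuts the three
preselected panels: Top40k (best marker per 55-kb window), ChipPlusSign
(chip + windowed significant variants at p <= 1e-6) and TopSign
(significant variants only).
"""

import numpy as np

from sspig import gwas, panels, pipeline, relmat, simdata

cfg = simdata.SimulationConfig(
    n_founders=100, n_generations=3, n_matings_per_gen=40, litter_size=6,
    n_seq_markers=2000, n_chip_markers=200, n_qtl=10,
    traits=("ADG",), heritabilities={"ADG": 0.4},
    litter_variance_fractions={"ADG": 0.1}, genetic_correlations=np.eye(1),
    seed=21,
)
line = pipeline.prepare_line(cfg, seed=21)
res = line.gwas_results["ADG"]
mm = line.population.marker_map

print(f"null model: h2 ratio = {res.null.heritability_ratio:.2f}")
n_sig = int((res.table["p_value"] <= 1e-6).sum())
qtl_ids = set(mm.marker_id[mm.is_qtl])
sig_ids = set(res.table.loc[res.table["p_value"] <= 1e-6, "marker"])
print(f"significant at 1e-6: {n_sig} markers, {len(sig_ids & qtl_ids)} of them QTL")

top = panels.select_top40k(res, mm)
cps = panels.select_chip_plus_sign(res, line.chip, mm)
ts = panels.select_top_sign(res, mm)
for p in (line.chip, top, cps, ts):
    hit = len(set(p.marker_ids) & qtl_ids)
    print(f"panel {p.name:15s}: {p.n:5d} markers, {hit} of {len(qtl_ids)} QTL captured")
# Top40k keeps one marker per occupied window whether or not it is
# significant; ChipPlusSign only adds windowed significant hits to the chip;
# TopSign is those hits alone and can be very small.
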