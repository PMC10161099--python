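"""Decompose endo-lysosomal disruption into its two mechanisms.

For each compound, Gal8 foci per cell are regressed on colloid uptake
(DiD puncta per cell) across wells; blocker wells, where endocytosis is
chemically inhibited, sit at zero uptake and anchor the intercept.  The
slope measures colloid-mediated disruption efficiency and the intercept
measures uptake-independent (free-drug) disruption.  Across a compound
panel, phospholipidosis tracks the intercept, not the slope.
"""

from colloidquant.mechanism import (
    PAIRING_EFFICIENCY,
    PAIRING_INTERCEPT,
    build_compound_summary,
    correlate_mechanism,
    fit_mechanism_panel,
)
from colloidquant.synthetic import (
    PanelSpec,
    generate_mechanism_panel,
    latent_driver_compounds,
)

compounds = latent_driver_compounds(15, seed=1)
panel = generate_mechanism_panel(
    PanelSpec(compounds=compounds, wells_per_compound=15, noise_sd=0.1,
              seed=1)
)
fits = fit_mechanism_panel(panel)

print("compound    slope (foci/punctum)   intercept (foci/cell)    R^2")
for f in fits[:5]:
    print(f"{f.compound:<12}{f.slope:>8.3f} +- {f.slope_se:<8.3f}"
          f"{f.intercept:>8.3f} +- {f.intercept_se:<8.3f}{f.r_squared:>6.3f}")
print(f"... ({len(fits)} compounds total)\n")

vesicles = panel.groupby("compound")["vesicles_per_cell"].mean().to_dict()
pka = {c.compound_id: c.pka for c in compounds}
join = build_compound_summary(fits, pka, vesicles)
r_int = correlate_mechanism(join.summaries, PAIRING_INTERCEPT)
r_eff = correlate_mechanism(join.summaries, PAIRING_EFFICIENCY)
print(f"r(phospholipidosis, intercept)  = {r_int.r:+.4f}  (n={r_int.n})")
print(f"r(phospholipidosis, efficiency) = {r_eff.r:+.4f}  (n={r_eff.n})")
print("\nThe strong intercept correlation and near-zero slope correlation")
print("indicate phospholipidosis is driven by free drug, not by colloid")
print("uptake.")
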