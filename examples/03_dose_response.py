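"""Fit mono- and biphasic dose-response curves to viability data.

Metabolic activity (%) versus drug concentration is fit with a Hill
inhibition curve; the biphasic form separates a sub-micromolar
growth-suppression (static) transition from a micromolar toxicity
transition via an intermediate plateau.
"""

import numpy as np

from colloidquant.curves import fit_dose_response
from colloidquant.synthetic import generate_dose_response

conc = np.concatenate([[0.0], np.logspace(-4, 2, 13)])  # uM

y = generate_dose_response(
    conc, dict(top=100.0, bottom=0.0, ic50=0.005, hill=1.0), "monophasic"
)
fit = fit_dose_response(conc, y, "monophasic")
print(f"monophasic:  IC50 = {fit.ic50 * 1000:.2f} nM,  Hill = {fit.hill:.2f},"
      f"  Top = {fit.top:.1f}%,  Bottom = {fit.bottom:.1f}%")

y2 = generate_dose_response(
    conc,
    dict(top=100.0, plateau=60.0, bottom=5.0, ic50_stat=0.003,
         hill_stat=1.2, ic50_tox=2.0, hill_tox=1.5),
    "biphasic",
)
fit2 = fit_dose_response(conc, y2, "biphasic")
print(f"biphasic:    IC50_stat = {fit2.ic50_stat * 1000:.2f} nM, "
      f"IC50_tox = {fit2.ic50_tox:.2f} uM, Plateau = {fit2.plateau:.1f}%")
print("\nIC50_stat is the midpoint of the growth-suppression transition;")
print("IC50_tox is the midpoint of the cytotoxic transition.")
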