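"""Macro-speciation of an antibiotic across soil pH.

Sulfamethoxazole (SMX) is a diprotic sulfonamide (pKa 1.83 / 5.62): in
acidic soils it is mostly neutral, and above pH ~5.6 the anion takes
over — which is why its sorption correlates negatively with soil pH.
"""

import soilptf as sp

compound = sp.get_compound("SMX")
print(f"{compound.code}: pKa = {compound.pka}, logKow = {compound.log_kow}")
print(f"{'pH':>4}  {'cation':>8}  {'neutral':>8}  {'anion':>8}")
for ph in (2.0, 4.0, 5.62, 7.0, 9.0):
    f = sp.species_fractions(compound, ph)
    print(f"{ph:>4}  {f.alpha_plus:8.4f}  {f.alpha_zero:8.4f}  {f.alpha_minus:8.4f}")

# At pH = pKa2 the neutral and anionic fractions are exactly equimolar;
# each row sums to 1 because the three classes exhaust the ladder.
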