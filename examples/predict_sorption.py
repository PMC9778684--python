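"""Estimate sorption coefficients for a soil from its routine properties.

Evaluates the built-in main pedotransfer functions (edaphic predictors
only) and one improved model that also uses the cation fraction, for a
moderately acidic agricultural soil.
"""

import soilptf as sp

soil = sp.SoilSample(pH=5.5, OC=2.4, CEC=150.0, sand=30.0, silt=35.0, clay=35.0)

for code in ("SCP", "SMT", "OTC", "CTC"):
    model = sp.get_builtin_model("table4", code, "Kf")
    pred = sp.predict(model, soil)
    flags = f"  [{', '.join(pred.flags)}]" if pred.flags else ""
    print(f"{code} Kf = {pred.value:9.2f} mg^(1-1/n) L^(1/n) kg^-1{flags}")

# Tetracyclines sorb orders of magnitude more strongly than sulfonamides;
# a negative raw value would be flagged, never silently clamped.

improved = sp.get_builtin_model("table5", "SCP", "Kd")
pred = sp.predict(improved, soil)  # alpha_plus computed from SCP's pKa at pH 5.5
print(f"SCP Kd (improved, species-aware) = {pred.value:.2f} L kg^-1")
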