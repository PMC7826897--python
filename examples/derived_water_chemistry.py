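"""Compute the three derived parameters from raw field measurements.

Unionized ammonia (the toxic NH3 fraction of TAN), relative dissolved
oxygen, and Fulton's condition factor are calculated, not measured; the
inputs below are the recorded values of two of the packaged farms.
"""

from fishwelfare import (
    FishMorphometrics,
    WaterChemInputs,
    fulton_condition_factor,
    oxygen_saturation,
    unionized_ammonia,
)

water = WaterChemInputs(temperature=11.5, pH=7.5, TAN=0.79, dissolved_oxygen=11.0)
print(f"NH3-N       : {unionized_ammonia(water):.4f} mg/L "
      "(toxic unionized fraction of 0.79 mg/L TAN at pH 7.5, 11.5 degC)")
print(f"O2 saturation: {oxygen_saturation(water):.0f} % of freshwater equilibrium")

fish = FishMorphometrics(standard_length=19.5, total_length=21.7, body_weight=132)
print(f"Fulton K     : {fulton_condition_factor(fish):.2f} "
      "(100*W/L^3; ~1 is typical, >1.5 suggests overconditioning in trout)")
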