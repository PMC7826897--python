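parameter_id,value,fish_index,unit
personnel_training,0,,
daily_check,0,,
treatment_journal,1,,
target_value_sheet,1,,
emergency_concept,1,,
hygiene_concept,1,,
mortality_documentation,1,,
biomass_documentation,0,,
predator_protection,NA,,
plant_cleanliness,0,,
stocking_density,1,,
sorting,0,,
slaughter,0,,
feeding_interval_rate,0,,
feed_type,0,,
disturbances,1,,
ambient_light,0,,
tank_light,0,,
carbonate_hardness,310,,CaCO3 mg/L
total_suspended_solids,10,,TSS mg/L
ammonium,0.79,,TAN mg/L
ammonia,0.005,,NH3-N mg/L
nitrite,0.12,,NO2-N mg/L
nitrate,7.29,,NO3-N mg/L
ph,7.5,,
conductivity,711,,uS/cm
temperature,11.5,,degC
oxygen,11,,O2 mg/L
oxygen_saturation,108,,O2 %
carbon_dioxide,21.8,,CO2 mg/L
total_gas_pressure,102,,%
water_velocity,0.3,,body lengths/s
aggression,0,,
territoriality,0,,
apathy,0,,
isolation,0,,
scratching,0,,
surfacing,2,,
air_gulping,0,,
ventilation_rate,0,,
fleeing,0,,
fin_position,0,,
balance,0,,
body_colour,1,,
feeding,1,,
jaw_deformations,0,,
gill_cover_deformations,0,,
spinal_deformations,0,,
eye_injuries,1,,
skin_injuries,2,,
fin_injuries,2,,
fungal_infections,0,,
body_condition_factor,1.5,,
mucus_pathogens,0,,
spinal_deformation,0,,
jaw_deformation,1,,
mouth_injury,1,,
skin_alterations,0,,
skin_fungus,0,,
skin_injury,0,,
cataract,0,,
eye_injury,1,,
exophthalmia,0,,
pectoral_fins,0,,
ventral_fins,1,,
anal_fin,0,,
caudal_fin,0,,
dorsal_fin,1,,
gill_cover,0,,
gills,0,,
heart,0,,
kidney,0,,
spleen,0,,
liver,0,,
intestines,0,,
muscles,0,,
reproductive_organs,0,,
gill_lamellae,0,,
gill_pathogens,0,,
body_cavity,0,,
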