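parameter_id,value,fish_index,unit
personnel_training,1,,
daily_check,0,,
treatment_journal,1,,
target_value_sheet,1,,
emergency_concept,1,,
hygiene_concept,1,,
mortality_documentation,2,,
biomass_documentation,1,,
predator_protection,1,,
plant_cleanliness,0,,
stocking_density,0,,
sorting,1,,
slaughter,0,,
feeding_interval_rate,0,,
feed_type,0,,
disturbances,1,,
ambient_light,NA,,
tank_light,1,,
carbonate_hardness,128,,CaCO3 mg/L
total_suspended_solids,5,,TSS mg/L
ammonium,NA,,TAN mg/L
ammonia,NA,,NH3-N mg/L
nitrite,NA,,NO2-N mg/L
nitrate,NA,,NO3-N mg/L
ph,7.75,,
conductivity,254,,uS/cm
temperature,7.4,,degC
oxygen,9.2,,O2 mg/L
oxygen_saturation,82,,O2 %
carbon_dioxide,1.6,,CO2 mg/L
total_gas_pressure,100,,%
water_velocity,0.4,,body lengths/s
aggression,0,,
territoriality,0,,
apathy,0,,
isolation,0,,
scratching,0,,
surfacing,0,,
air_gulping,0,,
ventilation_rate,0,,
fleeing,0,,
fin_position,0,,
balance,0,,
body_colour,0,,
feeding,0,,
jaw_deformations,0,,
gill_cover_deformations,0,,
spinal_deformations,0,,
eye_injuries,0,,
skin_injuries,0,,
fin_injuries,1,,
fungal_infections,0,,
body_condition_factor,1.4,,
mucus_pathogens,0,,
spinal_deformation,0,,
jaw_deformation,0,,
mouth_injury,0,,
skin_alterations,0,,
skin_fungus,0,,
skin_injury,0,,
cataract,0,,
eye_injury,0,,
exophthalmia,0,,
pectoral_fins,1,,
ventral_fins,1,,
anal_fin,1,,
caudal_fin,0,,
dorsal_fin,0,,
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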