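parameter_id,value,fish_index,unit
personnel_training,2,,
daily_check,0,,
treatment_journal,1,,
target_value_sheet,2,,
emergency_concept,2,,
hygiene_concept,1,,
mortality_documentation,2,,
biomass_documentation,2,,
predator_protection,2,,
plant_cleanliness,1,,
stocking_density,0,,
sorting,0,,
slaughter,1,,
feeding_interval_rate,0,,
feed_type,0,,
disturbances,0,,
ambient_light,NA,,
tank_light,1,,
carbonate_hardness,347,,CaCO3 mg/L
total_suspended_solids,20,,TSS mg/L
ammonium,NA,,TAN mg/L
ammonia,NA,,NH3-N mg/L
nitrite,NA,,NO2-N mg/L
nitrate,NA,,NO3-N mg/L
ph,7.61,,
conductivity,640,,uS/cm
temperature,14.8,,degC
oxygen,5.9,,O2 mg/L
oxygen_saturation,62,,O2 %
carbon_dioxide,5.5,,CO2 mg/L
total_gas_pressure,100,,%
water_velocity,0.3,,body lengths/s
aggression,1,,
territoriality,0,,
apathy,0,,
isolation,0,,
scratching,1,,
surfacing,0,,
air_gulping,1,,
ventilation_rate,2,,
fleeing,0,,
fin_position,0,,
balance,0,,
body_colour,0,,
feeding,0,,
jaw_deformations,4,,
gill_cover_deformations,2,,
spinal_deformations,0,,
eye_injuries,1,,
skin_injuries,1,,
fin_injuries,2,,
fungal_infections,0,,
body_condition_factor,1.6,,
mucus_pathogens,0,,
spinal_deformation,0,,
jaw_deformation,2,,
mouth_injury,1,,
skin_alterations,1,,
skin_fungus,0,,
skin_injury,0,,
cataract,0,,
eye_injury,1,,
exophthalmia,0,,
pectoral_fins,1,,
ventral_fins,0,,
anal_fin,0,,
caudal_fin,0,,
dorsal_fin,1,,
gill_cover,1,,
gills,1,,
heart,0,,
kidney,0,,
spleen,0,,
liver,0,,
intestines,0,,
muscles,0,,
reproductive_organs,0,,
gill_lamellae,2,,
gill_pathogens,1,,
body_cavity,0,,
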