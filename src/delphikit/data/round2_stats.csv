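indicator_id,label,primary_id,secondary_id,Mj,sd,Vj,Kj_pct,Cs,Ca,Cr
electric_scald_instrument,Electric scald instrument,methods_of_induction,high_temperature_solid,8.08,1.0,0.12,7.69,0.72,0.753,0.737
hydrothermal_flask,Hydrothermal flask,methods_of_induction,high_temperature_solid,6.38,1.86,0.29,7.69,0.6,0.72,0.66
water_bath_hot_steel_bar,Water bath hot steel bar,methods_of_induction,high_temperature_solid,5.77,1.89,0.33,7.69,0.56,0.693,0.627
hot_water_bath,Hot-water bath,methods_of_induction,high_temperature_liquid,7.38,1.44,0.2,7.69,0.68,0.76,0.72
water_spray_injury_cup,Water spray injury cup,methods_of_induction,high_temperature_liquid,5.38,1.69,0.31,0.0,0.48,0.653,0.567
water_bath_high_temperature_gauze,Water bath high temperature gauze,methods_of_induction,high_temperature_liquid,5.54,1.87,0.34,7.69,0.6,0.707,0.654
skin_application_fuel,Skin application fuel,methods_of_induction,contact_combustion,5.15,1.99,0.39,7.69,0.493,0.667,0.58
infrared_heater,Infrared heater,methods_of_induction,thermal_radiation,4.85,2.41,0.5,0.0,0.453,0.68,0.567
ionizing_radiation,Ionizing radiation,methods_of_induction,thermal_radiation,4.15,2.54,0.61,7.69,0.4,0.66,0.53
back,Back,burn_sites,,9.15,0.77,0.08,38.46,0.8,0.767,0.784
abdomen,Abdomen,burn_sites,,5.08,2.92,0.57,15.38,0.533,0.64,0.587
buttock,Buttock,burn_sites,,5.92,2.59,0.44,15.38,0.5467,0.66,0.603
less_than_80c,Less than 80 °C,induction_temperature,,8.62,0.84,0.1,15.38,0.707,0.773,0.74
between_80_and_100c,Between 80 and 100 °C,induction_temperature,,4.85,2.32,0.48,0.0,0.573,0.667,0.62
pentobarbital_sodium,Pentobarbital sodium,anesthesia,general_anesthesia,8.0,2.63,0.33,23.08,0.733,0.733,0.733
chloral_hydrate,Chloral hydrate,anesthesia,general_anesthesia,7.38,2.02,0.27,23.08,0.733,0.793,0.763
isoflurane,Isoflurane,anesthesia,general_anesthesia,5.23,2.97,0.57,0.0,0.387,0.64,0.514
diethyl_ether,Diethyl ether,anesthesia,general_anesthesia,5.46,2.44,0.45,0.0,0.533,0.667,0.6
uratan,Uratan,anesthesia,general_anesthesia,4.23,2.52,0.59,0.0,0.36,0.633,0.497
serazine,Serazine,anesthesia,general_anesthesia,3.08,1.98,0.64,0.0,0.32,0.593,0.457
barium_sulfide,Barium sulfide,skin_preparation,chemical_method,7.69,2.05,0.27,38.46,0.667,0.74,0.704
sodium_sulfide,Sodium sulfide,skin_preparation,chemical_method,6.08,2.53,0.42,7.69,0.427,0.687,0.557
razor,Razor,skin_preparation,physical_method,7.08,2.56,0.36,23.08,0.653,0.713,0.683
push_shear,Push shear,skin_preparation,physical_method,6.15,2.57,0.42,15.38,0.573,0.7,0.637
rearing_temperature,Rearing temperature,housing_post_surgery,rearing_environment,8.08,2.53,0.31,30.77,0.653,0.727,0.69
rearing_humidity,Rearing humidity,housing_post_surgery,rearing_environment,8.0,2.48,0.31,30.77,0.707,0.72,0.714
environmental_ventilation,Environmental ventilation,housing_post_surgery,rearing_environment,7.85,2.48,0.32,30.77,0.68,0.707,0.694
rearing_density,Rearing density,housing_post_surgery,rearing_environment,7.46,2.62,0.35,23.08,0.68,0.72,0.7
selection_of_bedding_material,Selection of bedding material,housing_post_surgery,rearing_environment,7.85,2.44,0.31,23.08,0.627,0.713,0.67
ambient_light,Ambient light,housing_post_surgery,rearing_environment,7.54,2.44,0.32,23.08,0.613,0.693,0.653
feed,Feed,housing_post_surgery,rearing_food,7.46,2.93,0.39,30.77,0.667,0.72,0.694
drinking_water,Drinking water,housing_post_surgery,rearing_food,7.46,2.93,0.39,30.77,0.667,0.713,0.69
lactate_ringers_solution,Lactate Ringer's solution,intervention_post_surgery,prevention_of_shock,7.62,2.56,0.34,23.08,0.667,0.693,0.68
hyperoxia_compound_sodium_chloride,Hyperoxia compound sodium chloride,intervention_post_surgery,prevention_of_shock,5.85,2.35,0.4,0.0,0.533,0.647,0.59
disinfection_of_animal_living_environment,Disinfection of animal living environment,intervention_post_surgery,prevention_of_infection,7.08,2.7,0.38,23.08,0.64,0.687,0.664
penicillin_cephalosporin,"Penicillin, generation I cephalosporin",intervention_post_surgery,prevention_of_infection,4.62,2.5,0.54,0.0,0.547,0.633,0.59
wound_color,Wound was pale,assessment_criteria,macroscopic_results,8.85,1.1,0.12,38.46,0.747,0.78,0.764
eschar_formation,Eschar formation,assessment_criteria,macroscopic_results,8.77,0.89,0.1,23.08,0.76,0.773,0.767
blister_formation,Blister formation,assessment_criteria,macroscopic_results,7.46,2.71,0.36,23.08,0.693,0.76,0.727
subcutaneous_injury,Subcutaneous injury,assessment_criteria,microscopic_results,9.15,0.77,0.08,28.46,0.76,0.787,0.774
dermal_injury,Dermal injury,assessment_criteria,microscopic_results,8.85,0.95,0.11,23.08,0.76,0.773,0.767
epidermis_injury,Epidermis injury,assessment_criteria,microscopic_results,8.85,0.86,0.1,23.08,0.773,0.787,0.78
success_rate_of_model_construction,Success rate of model construction,assessment_criteria,other_comments,8.69,0.82,0.09,15.38,0.733,0.773,0.753
incidence_of_complications,Incidence of complications,assessment_criteria,other_comments,8.23,1.37,0.17,15.38,0.72,0.747,0.734
mortality_of_rats,Mortality of rats,assessment_criteria,other_comments,8.31,1.07,0.13,15.38,0.733,0.753,0.743
model_building_resource_consumption,Model building resource consumption,assessment_criteria,other_comments,7.08,2.13,0.3,15.38,0.653,0.74,0.697
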