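indicator_id,label,primary_id,secondary_id,Mj,sd,Vj,Kj_pct,Cs,Ca,Cr
electric_scald_instrument,Electric scald instrument,methods_of_induction,high_temperature_solid,7.8,1.8,0.23,7.8,0.79,0.873,0.832
hydrothermal_flask,Hydrothermal flask,methods_of_induction,high_temperature_solid,5.0,2.4,0.48,5.0,0.45,0.787,0.619
water_bath_hot_steel_bar,Water bath hot steel bar,methods_of_induction,high_temperature_solid,5.73,2.05,0.36,5.73,0.59,0.827,0.709
hot_water_bath,Hot-water bath,methods_of_induction,high_temperature_liquid,7.33,1.62,0.22,7.33,0.77,0.9,0.835
water_spray_injury_cup,Water spray injury cup,methods_of_induction,high_temperature_liquid,5.13,2.36,0.46,5.13,0.49,0.78,0.635
water_bath_high_temperature_gauze,Water bath high temperature gauze,methods_of_induction,high_temperature_liquid,5.27,2.14,0.41,5.27,0.55,0.78,0.665
skin_application_fuel,Skin application fuel,methods_of_induction,contact_combustion,4.67,2.67,0.57,4.67,0.51,0.813,0.662
infrared_heater,Infrared heater,methods_of_induction,thermal_radiation,4.67,2.82,0.6,4.67,0.47,0.78,0.625
back,Back,burn_sites,,9.07,1.34,0.15,9.07,0.92,0.927,0.924
abdomen,Abdomen,burn_sites,,5.0,3.18,0.64,5.0,0.52,0.813,0.667
buttock,Buttock,burn_sites,,3.93,3.04,0.77,3.93,0.4,0.747,0.574
less_than_80c,Less than 80 °C,induction_temperature,,4.93,2.86,0.58,4.93,0.64,0.853,0.747
between_80_and_100c,Between 80 and 100 °C,induction_temperature,,8.4,1.25,0.15,8.4,0.77,0.94,0.856
more_than_200c,More than 200 °C,induction_temperature,,3.4,3.44,1.01,3.4,0.32,0.753,0.537
pentobarbital_sodium,Pentobarbital sodium,anesthesia,general_anesthesia,7.67,2.89,0.38,7.67,0.85,0.913,0.882
chloral_hydrate,Chloral hydrate,anesthesia,general_anesthesia,6.2,2.76,0.45,6.2,0.67,0.84,0.755
ketamine,Ketamine,anesthesia,general_anesthesia,4.13,2.99,0.72,4.13,0.36,0.76,0.56
isoflurane,Isoflurane,anesthesia,general_anesthesia,5.73,3.43,0.6,5.73,0.44,0.813,0.627
serazine,Serazine,anesthesia,general_anesthesia,2.87,2.03,0.71,2.87,0.23,0.713,0.472
uratan,Uratan,anesthesia,general_anesthesia,3.73,2.86,0.77,3.73,0.32,0.753,0.537
diethyl_ether,Diethyl ether,anesthesia,general_anesthesia,5.4,3.09,0.57,5.4,0.51,0.847,0.679
lidocaine,Lidocaine,anesthesia,local_anesthesia,3.87,3.56,0.92,3.87,0.45,0.767,0.609
bupivacaine,Bupivacaine,anesthesia,local_anesthesia,3.27,2.89,0.88,3.27,0.27,0.707,0.489
barium_sulfide,Barium sulfide,skin_preparation,chemical_method,4.67,2.98,0.64,4.67,0.39,0.787,0.589
sodium_sulfide,Sodium sulfide,skin_preparation,chemical_method,6.8,3.23,0.47,6.8,0.75,0.873,0.812
razor,Razor,skin_preparation,physical_method,4.73,3.84,0.81,4.73,0.49,0.78,0.635
push_shear,Push shear,skin_preparation,physical_method,6.8,3.19,0.47,6.8,0.71,0.867,0.789
rearing_temperature,Rearing temperature,housing_post_surgery,rearing_environment,8.13,2.78,0.34,8.13,0.81,0.92,0.865
rearing_humidity,Rearing humidity,housing_post_surgery,rearing_environment,8.07,2.79,0.35,8.07,0.8,0.92,0.86
environmental_ventilation,Environmental ventilation,housing_post_surgery,rearing_environment,7.87,2.78,0.35,7.87,0.79,0.9,0.845
ambient_light,Ambient light,housing_post_surgery,rearing_environment,7.2,3.06,0.42,7.2,0.73,0.907,0.819
rearing_density,Rearing density,housing_post_surgery,rearing_environment,8.07,2.74,0.34,8.07,0.8,0.913,0.857
selection_of_bedding_material,Selection of bedding material,housing_post_surgery,rearing_environment,7.53,3.12,0.41,7.53,0.73,0.907,0.819
feed,Feed,housing_post_surgery,rearing_food,6.73,3.45,0.51,6.73,0.73,0.9,0.815
drinking_water,Drinking water,housing_post_surgery,rearing_food,7.13,3.32,0.47,7.13,0.77,0.907,0.839
lactate_ringers_solution,Lactate Ringer's solution,intervention_post_surgery,prevention_of_shock,6.87,3.4,0.5,6.87,0.71,0.88,0.795
hyperoxia_compound_sodium_chloride,Hyperoxia compound sodium chloride,intervention_post_surgery,prevention_of_shock,4.53,3.54,0.78,4.53,0.35,0.74,0.545
disinfection_of_animal_living_environment,Disinfection of animal living environment,intervention_post_surgery,prevention_of_shock,7.07,3.47,0.49,7.07,0.75,0.88,0.815
vaccination,Vaccination,intervention_post_surgery,prevention_of_infection,2.07,2.35,1.14,2.07,0.24,0.68,0.46
penicillin_cephalosporin,"Penicillin, generation I cephalosporin",intervention_post_surgery,prevention_of_infection,5.0,3.69,0.74,5.0,0.6,0.807,0.704
analgin,Analgin,intervention_post_surgery,prevention_of_infection,3.4,3.28,0.97,3.4,0.44,0.727,0.584
lappaconitine,Lappaconitine,intervention_post_surgery,analgesia,2.73,2.86,1.05,2.73,0.32,0.72,0.52
dexmedetomidine,Dexmedetomidine,intervention_post_surgery,analgesia,2.8,2.97,1.06,2.8,0.31,0.707,0.509
wound_color,Wound color,assessment_criteria,macroscopic_results,8.73,1.53,0.17,8.73,0.88,0.94,0.91
blister_formation,Blister formation,assessment_criteria,macroscopic_results,7.67,2.57,0.34,7.67,0.8,0.9,0.85
eschar_formation,Eschar formation,assessment_criteria,macroscopic_results,8.53,1.63,0.19,8.53,0.88,0.927,0.904
epidermis_injury,Epidermis injury,assessment_criteria,microscopic_results,7.53,3.05,0.41,7.53,0.87,0.94,0.905
dermal_injury,Dermal injury,assessment_criteria,microscopic_results,8.13,2.31,0.28,8.13,0.84,0.927,0.884
subcutaneous_injury,Subcutaneous injury,assessment_criteria,microscopic_results,8.67,1.74,0.2,8.67,0.87,0.927,0.899
success_rate_of_model_construction,Success rate of model construction,assessment_criteria,other_comments,8.47,1.54,0.18,8.47,0.83,0.927,0.879
model_construction_time_consumption,Model construction time consumption,assessment_criteria,other_comments,7.33,2.36,0.32,7.33,0.84,0.92,0.88
model_building_resource_consumption,Model building resource consumption,assessment_criteria,other_comments,6.87,2.7,0.39,6.87,0.76,0.88,0.82
mortality_of_rats,Mortality of rats,assessment_criteria,other_comments,8.07,1.95,0.24,8.07,0.79,0.907,0.849
incidence_of_complications,Incidence of complications,assessment_criteria,other_comments,7.93,2.24,0.28,7.93,0.75,0.893,0.822
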