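id,label,tier,parent_id,status,origin_round
methods_of_induction,Methods of induction,1,,active,0
burn_sites,Burn sites,1,,active,0
induction_temperature,Induction temperature,1,,active,0
anesthesia,Anesthesia,1,,active,0
skin_preparation,Skin preparation,1,,active,0
housing_post_surgery,Housing post surgery,1,,active,0
intervention_post_surgery,Intervention post surgery,1,,active,0
assessment_criteria,Assessment criteria,1,,active,0
high_temperature_solid,High temperature solid,2,methods_of_induction,active,0
high_temperature_liquid,High temperature liquid,2,methods_of_induction,active,0
contact_combustion,Contact combustion,2,methods_of_induction,active,0
thermal_radiation,Thermal radiation,2,methods_of_induction,active,0
general_anesthesia,General anesthesia,2,anesthesia,active,0
local_anesthesia,Local anesthesia,2,anesthesia,active,0
chemical_method,Chemical method,2,skin_preparation,active,0
physical_method,Physical method,2,skin_preparation,active,0
rearing_environment,Rearing environment,2,housing_post_surgery,active,0
rearing_food,Rearing food,2,housing_post_surgery,active,0
prevention_of_shock,Prevention of shock,2,intervention_post_surgery,active,0
prevention_of_infection,Prevention of infection,2,intervention_post_surgery,active,0
analgesia,Analgesia,2,intervention_post_surgery,active,0
macroscopic_results,Macroscopic results,2,assessment_criteria,active,0
microscopic_results,Microscopic results,2,assessment_criteria,active,0
other_comments,Other comments,2,assessment_criteria,active,0
electric_scald_instrument,Electric scald instrument,3,high_temperature_solid,active,0
hydrothermal_flask,Hydrothermal flask,3,high_temperature_solid,active,0
water_bath_hot_steel_bar,Water bath hot steel bar,3,high_temperature_solid,active,0
hot_water_bath,Hot-water bath,3,high_temperature_liquid,active,0
water_spray_injury_cup,Water spray injury cup,3,high_temperature_liquid,active,0
water_bath_high_temperature_gauze,Water bath high temperature gauze,3,high_temperature_liquid,active,0
skin_application_fuel,Skin application fuel,3,contact_combustion,active,0
infrared_heater,Infrared heater,3,thermal_radiation,active,0
back,Back,3,burn_sites,active,0
abdomen,Abdomen,3,burn_sites,active,0
buttock,Buttock,3,burn_sites,active,0
less_than_80c,Less than 80 °C,3,induction_temperature,active,0
between_80_and_100c,Between 80 and 100 °C,3,induction_temperature,active,0
more_than_200c,More than 200 °C,3,induction_temperature,active,0
pentobarbital_sodium,Pentobarbital sodium,3,general_anesthesia,active,0
chloral_hydrate,Chloral hydrate,3,general_anesthesia,active,0
ketamine,Ketamine,3,general_anesthesia,active,0
isoflurane,Isoflurane,3,general_anesthesia,active,0
serazine,Serazine,3,general_anesthesia,active,0
uratan,Uratan,3,general_anesthesia,active,0
diethyl_ether,Diethyl ether,3,general_anesthesia,active,0
lidocaine,Lidocaine,3,local_anesthesia,active,0
bupivacaine,Bupivacaine,3,local_anesthesia,active,0
barium_sulfide,Barium sulfide,3,chemical_method,active,0
sodium_sulfide,Sodium sulfide,3,chemical_method,active,0
razor,Razor,3,physical_method,active,0
push_shear,Push shear,3,physical_method,active,0
rearing_temperature,Rearing temperature,3,rearing_environment,active,0
rearing_humidity,Rearing humidity,3,rearing_environment,active,0
environmental_ventilation,Environmental ventilation,3,rearing_environment,active,0
ambient_light,Ambient light,3,rearing_environment,active,0
rearing_density,Rearing density,3,rearing_environment,active,0
selection_of_bedding_material,Selection of bedding material,3,rearing_environment,active,0
feed,Feed,3,rearing_food,active,0
drinking_water,Drinking water,3,rearing_food,active,0
lactate_ringers_solution,Lactate Ringer's solution,3,prevention_of_shock,active,0
hyperoxia_compound_sodium_chloride,Hyperoxia compound sodium chloride,3,prevention_of_shock,active,0
disinfection_of_animal_living_environment,Disinfection of animal living environment,3,prevention_of_shock,active,0
vaccination,Vaccination,3,prevention_of_infection,active,0
penicillin_cephalosporin,"Penicillin, generation I cephalosporin",3,prevention_of_infection,active,0
analgin,Analgin,3,prevention_of_infection,active,0
lappaconitine,Lappaconitine,3,analgesia,active,0
dexmedetomidine,Dexmedetomidine,3,analgesia,active,0
wound_color,Wound color,3,macroscopic_results,active,0
blister_formation,Blister formation,3,macroscopic_results,active,0
eschar_formation,Eschar formation,3,macroscopic_results,active,0
epidermis_injury,Epidermis injury,3,microscopic_results,active,0
dermal_injury,Dermal injury,3,microscopic_results,active,0
subcutaneous_injury,Subcutaneous injury,3,microscopic_results,active,0
success_rate_of_model_construction,Success rate of model construction,3,other_comments,active,0
model_construction_time_consumption,Model construction time consumption,3,other_comments,active,0
model_building_resource_consumption,Model building resource consumption,3,other_comments,active,0
mortality_of_rats,Mortality of rats,3,other_comments,active,0
incidence_of_complications,Incidence of complications,3,other_comments,active,0
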