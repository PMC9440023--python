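round,action,indicator_id,label,tier,parent_id,note
1,delete,local_anesthesia,Local anesthesia,2,anesthesia,secondary group removed after panel review
1,delete,analgesia,Analgesia,2,intervention_post_surgery,secondary group removed after panel review
1,delete,more_than_200c,More than 200 °C,3,induction_temperature,failed boundary screen
1,delete,ketamine,Ketamine,3,general_anesthesia,failed boundary screen
1,delete,lidocaine,Lidocaine,3,local_anesthesia,parent group removed
1,delete,bupivacaine,Bupivacaine,3,local_anesthesia,parent group removed
1,delete,vaccination,Vaccination,3,prevention_of_infection,failed boundary screen
1,delete,analgin,Analgin,3,prevention_of_infection,failed boundary screen
1,delete,lappaconitine,Lappaconitine,3,analgesia,parent group removed
1,delete,dexmedetomidine,Dexmedetomidine,3,analgesia,parent group removed
1,delete,model_construction_time_consumption,Model construction time consumption,3,other_comments,merged into resource consumption on expert advice (expert-override)
1,add,ionizing_radiation,Ionizing radiation,3,thermal_radiation,new induction method proposed by panel
1,rename,wound_color,Wound was pale,3,macroscopic_results,label clarified by panel
1,move,disinfection_of_animal_living_environment,Disinfection of animal living environment,3,prevention_of_infection,regrouped under infection prevention
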