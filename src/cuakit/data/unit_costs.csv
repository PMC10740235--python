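category,item,unit,unit_cost_eur
inpatient,psychiatric_inpatient_day,day,505.40
inpatient,pediatric_inpatient_day,day,420.00
outpatient,psychiatrist_contact,contact,66.36
outpatient,psychotherapist_contact,contact,88.56
outpatient,pediatrician_contact,contact,42.00
institutional_welfare,residential_care_day,day,180.00
institutional_welfare,day_group_care_day,day,95.00
ambulant_welfare,family_support_contact,contact,55.00
ambulant_welfare,social_worker_contact,contact,48.00
medication,psychotropic_pack,pack,35.00
medication,other_medication_pack,pack,18.00
school_based,school_psychologist_contact,contact,60.00
school_based,integration_assistant_hour,hour,28.00
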