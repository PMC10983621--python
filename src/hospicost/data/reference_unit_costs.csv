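activity_code,level,unit,unit_cost_no_dep,unit_cost_with_dep
surgery_hospitalization,provincial,hospitalization_day,58.49,74.93
surgery_hospitalization,regional,hospitalization_day,73.43,83.15
surgery_hospitalization,teaching,hospitalization_day,79.41,88.03
medicine_hospitalization,provincial,hospitalization_day,61.14,68.41
medicine_hospitalization,regional,hospitalization_day,74.69,82.06
medicine_hospitalization,teaching,hospitalization_day,67.64,74.62
maternity,provincial,hospitalization_day,66.48,73.25
maternity,regional,hospitalization_day,81.41,91.63
maternity,teaching,hospitalization_day,74.33,84.69
neonatology,provincial,hospitalization_day,38.69,42.50
neonatology,regional,hospitalization_day,81.13,93.47
neonatology,teaching,hospitalization_day,127.26,133.29
pediatrics,provincial,hospitalization_day,38.02,43.47
pediatrics,regional,hospitalization_day,91.08,102.03
pediatrics,teaching,hospitalization_day,96.71,103.43
psychiatry,provincial,hospitalization_day,27.44,29.96
psychiatry,regional,hospitalization_day,25.99,30.13
psychiatry,teaching,hospitalization_day,59.11,62.68
icu,provincial,hospitalization_day,149.75,183.06
icu,regional,hospitalization_day,319.67,465.40
icu,teaching,hospitalization_day,394.83,453.94
emergency,provincial,consultation,14.15,15.53
emergency,regional,consultation,13.86,16.59
emergency,teaching,consultation,64.92,69.86
outpatient_consultation,provincial,consultation,29.27,30.72
outpatient_consultation,regional,consultation,28.72,29.72
outpatient_consultation,teaching,consultation,39.69,42.71
radiology,provincial,unit_Z,1.00,1.49
radiology,regional,unit_Z,0.57,0.92
radiology,teaching,unit_Z,0.44,0.52
laboratory,provincial,unit_B,0.13,0.17
laboratory,regional,unit_B,0.08,0.11
laboratory,teaching,unit_B,0.07,0.07
operating_theater,provincial,unit_K,6.75,7.57
operating_theater,regional,unit_K,5.76,8.20
operating_theater,teaching,unit_K,2.59,3.07
hemodialysis,provincial,hemodialysis_session,56.21,64.92
hemodialysis,regional,hemodialysis_session,62.07,73.31
hemodialysis,teaching,hemodialysis_session,182.68,186.15
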