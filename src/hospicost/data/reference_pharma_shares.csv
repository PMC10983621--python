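activity_code,pharma_share
medicine_hospitalization,0.31
surgery_hospitalization,0.15
maternity,0.13
pediatrics,0.33
icu,0.26
neonatology,0.20
psychiatry,0.03
outpatient_consultation,0.06
hemodialysis,0.22
oncology,0.56
emergency,0.20
radiology,0.19
laboratory,0.60
operating_theater,0.20
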