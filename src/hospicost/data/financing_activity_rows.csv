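level,activity_code,cost_per_admission,frequency_pct,inpatient_count,printed_total
teaching,surgery_hospitalization,2690.09,23.19,71127,191340034.88
teaching,maternity,195.19,36.65,112405,21940268.00
teaching,medicine_hospitalization,1978.48,20.67,63403,125442839.96
teaching,oncology,10681.18,1.10,3367,35963978.95
teaching,pediatrics,873.08,9.45,28994,25314065.00
teaching,icu,2113.95,8.94,27407,57938942.66
regional,surgery_hospitalization,626.52,23.19,71127,35837714.14
regional,maternity,108.86,36.65,112405,8987792.61
regional,medicine_hospitalization,493.61,20.67,63403,16970667.65
regional,pediatrics,157.45,9.45,28994,5861897.66
regional,icu,1323.68,8.94,27407,8003759.01
provincial,surgery_hospitalization,577.53,23.19,71128,64505236.12
provincial,maternity,109.41,36.65,112405,28814455.06
provincial,medicine_hospitalization,284.16,20.67,63404,42810286.92
provincial,pediatrics,115.98,9.45,28994,13024269.03
provincial,icu,335.12,8.94,27408,9220937.35
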