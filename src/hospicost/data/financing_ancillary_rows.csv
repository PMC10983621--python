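level,activity_code,unit_cost,units_per_inpatient,printed_total
teaching,laboratory,0.08,2529,59185229.65
teaching,radiology,0.52,165,26527775.70
regional,laboratory,0.07,2529,10073955.05
regional,radiology,0.86,165,12256730.31
provincial,laboratory,0.15,2529,23471282.34
provincial,radiology,0.73,165,18104484.09
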