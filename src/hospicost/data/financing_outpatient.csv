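activity_code,unit_cost,total_consultations,printed_total
outpatient_consultation,21.05,3855107,81160148.25
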