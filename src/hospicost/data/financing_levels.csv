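level,total_inpatients,printed_level_total
teaching,306706,814273550.81
regional,217419,97992516.80
provincial,665517,199950950.91
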