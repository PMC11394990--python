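variable_name,type,include
city,qualitative,True
channel,qualitative,True
aux_q01,quantitative,True
aux_q02,quantitative,True
aux_q03,quantitative,True
aux_q04,quantitative,True
aux_q05,quantitative,True
aux_q06,quantitative,True
aux_q07,quantitative,True
aux_q08,quantitative,True
aux_q09,quantitative,True
aux_q10,quantitative,True
aux_q11,quantitative,True
aux_q12,quantitative,True
aux_q13,quantitative,True
aux_q14,quantitative,True
aux_c01,qualitative,True
aux_c02,qualitative,True
aux_c03,qualitative,True
aux_c04,qualitative,True
aux_c05,qualitative,True
aux_c06,qualitative,True
aux_c07,qualitative,True
aux_c08,qualitative,True
aux_c09,qualitative,True
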