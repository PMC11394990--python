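project_id,min_limit,max_limit,unit,limit_kind
P001,0.0,0.1179,mg/L,max_only
P002,1.071,1.071,mg/kg,point
P003,0.240193,0.8559,mg/kg,band
P004,0.0,6.8287,mg/L,max_only
P005,0.0,1.8132,mg/L,max_only
P006,1.0672,1.0672,mg/L,point
P007,0.0,0.9857,mg/kg,max_only
P008,0.054736,0.3126,mg/kg,band
P009,0.053663,0.1056,mg/kg,band
P010,0.0,0.2426,mg/L,max_only
P011,0.0,2.4214,mg/kg,max_only
P012,0.0,0.2519,mg/kg,max_only
P013,0.0,0.5484,mg/L,max_only
P014,0.0,0.1017,mg/kg,max_only
P015,0.0,4.5719,mg/kg,max_only
P016,0.0,0.2037,mg/kg,max_only
P017,0.0,0.0,mg/kg,exact_zero
P018,1.266648,5.7632,mg/kg,band
P019,0.0,1.0461,mg/kg,max_only
P020,0.0,0.0,mg/L,exact_zero
P021,0.0,1.903,mg/kg,max_only
P022,0.0,3.0447,mg/kg,max_only
P023,0.0,0.1524,mg/kg,max_only
P024,0.0,1.2086,mg/kg,max_only
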