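project_id,score
P001,1
P002,1
P003,4
P004,2
P005,5
P006,1
P007,5
P008,1
P009,3
P010,5
P011,1
P012,4
P013,4
P014,3
P015,1
P016,3
P017,3
P018,5
P019,4
P020,2
P021,1
P022,3
P023,2
P024,4
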