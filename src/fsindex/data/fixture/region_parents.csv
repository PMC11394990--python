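region,parent
city-A,region-X
city-B,region-X
city-C,region-X
city-D,region-X
city-E,region-X
city-F,region-X
city-G,region-X
city-H,region-X
city-I,region-X
city-J,region-X
city-K,region-X
city-L,region-X
city-M,region-X
city-N,region-X
city-O,region-X
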