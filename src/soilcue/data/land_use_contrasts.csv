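pair_id,region,management_low,ph_low,c_low,management_high,ph_high,c_high
1,Hertfordshire,Unimproved grassland since 1949,6.4,3.7,Intensive: arable,6.4,1.6
2,Hertfordshire,Unimproved grassland since 1949,6.6,2.8,Intensive: arable,6.9,1.5
3,Hertfordshire,Unimproved grassland since 1900,6.8,4,Intensive: arable,7.5,1
4,Bedfordshire,Unimproved grassland since 2002,7,1.5,Intensive: arable,7.2,1
5,Oxfordshire,Unimproved grassland since 1990,6.9,2.9,Intensive: arable,7.4,2.3
6,Oxfordshire,Unimproved grassland,7.5,6.3,Intensive: arable,7.7,2.1
7,Oxfordshire,Unimproved wet grassland,7.6,15.7,Intensive grassland,7.6,8.8
8,Cambridgeshire,Unimproved grassland,7.6,7.4,Intensive: arable,7.9,4
9,Devon,Unimproved grassland,6.7,5.1,Intensive: arable,6.6,4.2
10,Lancashire,Unimproved grassland since before 1980,6.7,6.3,Intensive grassland,6.9,5
11,Wiltshire,Unimproved calcareous grassland since before 1900,7.7,10.4,Intensive: arable,8,3.8
12,North Lanarkshire,Unimproved grassland since before 1985,5.8,6.9,Intensive: arable,6.4,3.8
13,Devon,Unimproved wet grassland,5.7,13,Intensive grassland,6.4,9.4
14,Devon,Unimproved wet grassland,5.3,13,Intensive grassland,6.4,5.7
15,Buckinghamshire,Unimproved grassland,6.1,5.9,Intensive: arable,7.7,3.6
16,Dorset,Unimproved grassland,5.8,3.9,Intensive grassland,6.8,3.7
17,Perthshire,Unimproved grassland,5.2,23.8,Intensive grassland,6.4,4.3
18,North Yorkshire,Unimproved grassland,5.9,9,Intensive grassland,5.8,7.6
19,Devon,Unimproved wet grassland,5.3,9.8,Intensive grassland,5.7,10.4
20,Devon,Unimproved wet grassland,5.8,17,Intensive grassland,5.8,4.3
21,Dorset,Unimproved grassland,5.6,5.2,Intensive grassland,6.2,3.7
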