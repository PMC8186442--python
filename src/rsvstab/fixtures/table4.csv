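unit,2020-12-16,2020-12-17,2020-12-18,2020-12-19,2020-12-20,2020-12-21,2020-12-22,2020-12-23,2020-12-24,2020-12-25,2020-12-26
Bangalore,60,63,63,59,63,60,62,63,61,62,61
Bogotá,48,49,,,,49,50,49,,,
Chicago,62,,,63,62,62,62,63,,,64
Mexico city,50,49,50,49,51,51,49,49,51,49,50
Dubai,,,,,,,,,,71,
Houston,,,52,54,,,51,,53,,
Hyderabad,43,,,,,,,,,,
London,66,67,67,67,67,67,65,66,64,66,67
Los angeles,58,60,59,60,60,60,58,57,,58,61
Madrid,80,82,82,85,81,84,80,78,80,80,84
Melbourne,87,88,86,88,84,87,85,83,85,85,88
Milan,97,100,98,97,100,100,94,100,100,97,100
Mumbai,73,74,70,71,69,72,72,71,72,71,72
New York,52,51,51,50,52,50,50,50,52,51,50
New Delhi,59,60,56,58,59,59,58,59,56,57,59
Paris,70,71,71,73,70,71,69,72,70,73,72
Rome,100,98,100,100,98,100,100,100,97,100,100
Sao paulo,,,32,,33,33,34,,34,33,
Santiago of Chile,43,,,44,,,,44,,,44
Singapore,56,56,56,56,58,57,55,57,56,55,58
Sydney,61,60,61,60,59,60,60,58,60,61,61
Toronto,81,80,78,79,79,82,77,81,78,79,79
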