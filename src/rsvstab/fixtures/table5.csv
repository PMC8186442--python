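unit,2020-12-16,2020-12-17,2020-12-18,2020-12-19,2020-12-20,2020-12-21,2020-12-22,2020-12-23,2020-12-24,2020-12-25,2020-12-26,2020-12-27
Bangalore,67,67,65,67,65,66,66,66,70,68,65,65
Bogotá,50,52,49,51,,50,,51,52,53,50,48
Chicago,61,62,60,,,60,,59,63,62,,
Mexico city,46,46,45,,,,48,46,47,,46,
Houston,53,53,50,,51,52,,,,,,52
Hyderabad,,49,48,49,48,,,,,50,,
London,64,64,64,63,64,65,66,64,67,65,63,62
Los angeles,58,58,55,57,56,58,56,56,60,57,56,57
Madrid,83,85,85,83,82,85,86,84,84,86,83,87
Melbourne,60,61,60,58,58,60,59,58,62,64,58,60
Milan,100,100,100,100,100,100,100,100,100,,100,100
Mumbai,78,77,75,76,76,76,76,78,78,80,77,77
New York,53,56,56,51,52,56,54,54,55,55,53,54
New Delhi,61,62,60,62,59,60,60,61,61,63,61,61
Paris,69,71,70,70,69,70,71,70,71,71,68,69
Rome,91,94,91,,92,,93,94,96,100,91,98
Sao paulo,34,34,32,,33,35,35,32,36,,,33
Santiago of Chile,45,,47,,46,,48,,,,46,
Singapore,55,57,58,57,56,58,57,59,58,60,58,57
Sydney,55,56,56,56,54,55,55,56,57,59,55,57
Toronto,72,72,70,71,71,72,72,70,75,71,70,70
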