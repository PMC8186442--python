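unit,2020-12-14,2020-12-15,2020-12-16,2020-12-17,2020-12-18,2020-12-19,2020-12-20,2020-12-21,2020-12-22,2020-12-23,2020-12-24,2020-12-25,2020-12-26
Bari,94,98,94,94,97,95,94,96,94,95,91,91,94
Bologna,94,92,96,94,96,95,95,96,95,94,90,91,94
Brescia,89,91,87,88,87,89,90,86,88,88,85,86,87
Cagliari,97,98,100,96,97,95,94,98,96,96,97,91,98
Catania,88,89,86,82,86,86,89,85,85,88,84,83,87
Firenze,96,100,98,100,100,97,100,99,97,98,100,95,97
Genova,88,92,89,91,89,91,89,92,90,90,89,86,87
Milano,89,94,90,90,91,91,91,91,86,93,90,88,90
Modena,,95,,92,,95,,,,,,,94
Napoli,89,93,89,88,91,90,91,87,90,94,88,84,89
Padova,88,90,88,87,91,88,87,84,87,89,87,84,87
Palermo,79,84,79,80,81,80,78,78,80,78,79,79,81
Parma,87,88,,,89,87,,86,85,86,87,,
Perugia,100,,,,,,98,100,100,,,100,100
Prato,,,,,,100,100,,,,,95,
Reggio calabria,,,,,,,,95,,100,96,,
Reggio emilia,,,88,,90,,,,,,,,
Roma,90,94,92,93,94,93,92,93,92,94,92,88,92
Salerno,,,87,86,87,84,,,85,88,85,,85
Taranto,,,,,,100,,,,,,,
Torino,92,92,95,91,96,88,96,90,87,97,88,88,87
Trieste,90,88,91,92,90,91,93,92,85,90,90,88,86
Venezia,82,85,83,81,80,83,81,82,79,84,80,79,80
Verona,83,85,86,81,86,86,86,84,82,84,82,79,82
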