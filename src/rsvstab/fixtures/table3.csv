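unit,2020-12-14,2020-12-15,2020-12-16,2020-12-17,2020-12-18,2020-12-19,2020-12-20,2020-12-21,2020-12-22,2020-12-23,2020-12-24,2020-12-25,2020-12-26
Bari,93,90,89,90,90,91,90,87,92,88,87,90,87
Bologna,96,95,96,95,95,96,95,92,95,92,92,98,95
Brescia,93,93,92,93,94,92,94,92,88,90,94,91,90
Cagliari,100,100,98,,100,100,100,100,100,100,100,100,100
Catania,89,87,89,89,89,87,88,91,94,86,88,89,86
Firenze,93,93,95,96,95,96,96,97,97,94,93,96,93
Genova,88,87,86,88,89,89,89,86,89,83,85,89,86
Messina,,,,,77,,,,,,,,
Milano,97,98,100,100,95,95,98,97,96,94,96,98,96
Modena,,,,,89,,,94,93,92,93,,
Napoli,90,89,90,90,88,88,87,86,87,87,88,87,84
Padova,93,92,93,,92,93,90,94,95,90,91,90,91
Palermo,78,77,79,77,77,79,81,79,79,75,78,78,74
Parma,,,,,,,,,,83,86,,
Perugia,,,,,,,,,,97,,,
Pescara,,,,,,,,,95,,,,
Prato,,,,,,,,,,,,91,
Reggio emilia,87,,,,86,,,,,,,84,
Roma,90,91,92,93,89,90,91,90,89,90,89,90,89
Salerno,,,86,,,,,,,,,,
Torino,93,92,94,95,91,92,94,94,94,92,94,91,92
Trieste,90,92,90,91,86,89,91,89,89,89,86,89,89
Venezia,91,89,93,91,89,91,89,94,87,88,88,87,87
Verona,,,,89,,87,90,,88,,89,,
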