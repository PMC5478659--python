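island,n_transects,high_individuals,high_species,low_individuals,low_species
Faial,8,5450,59,1415,39
Flores,12,9845,83,2161,39
Pico,16,17127,93,4970,52
Santa Maria,4,4303,63,786,33
Sao Jorge,8,9043,84,2081,37
Sao Miguel,12,6923,101,2601,48
Terceira,39,23973,124,11850,57
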