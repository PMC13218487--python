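language,meaning,cognate_id,value
Slovene,two,two_dwo,1
Slovene,belly,belly_terh1,1
Slovene,belly,belly_bhreus,0
Slovene,belly,belly_gweh3,0
Slovene,belly,belly_kwehl,0
Polish,two,two_dwo,1
Polish,belly,belly_terh1,0
Polish,belly,belly_bhreus,1
Polish,belly,belly_gweh3,0
Polish,belly,belly_kwehl,0
Czech,two,two_dwo,1
Czech,belly,belly_terh1,0
Czech,belly,belly_bhreus,1
Czech,belly,belly_gweh3,0
Czech,belly,belly_kwehl,0
Ukrainian,two,two_dwo,1
Ukrainian,belly,belly_terh1,0
Ukrainian,belly,belly_bhreus,0
Ukrainian,belly,belly_gweh3,1
Ukrainian,belly,belly_kwehl,0
Rusyn,two,two_dwo,1
Rusyn,belly,belly_terh1,0
Rusyn,belly,belly_bhreus,0
Rusyn,belly,belly_gweh3,0
Rusyn,belly,belly_kwehl,1
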