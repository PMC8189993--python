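species_code,binomial,superfamily,family,subfamily,pest,published_group,published_habit,fig23_group,specialist_sublabel,habitat_flags
AC204,Acarus chaetoxysilos,Acaroidea,Acaridae,Acarinae,False,fragmentary,interstitial,fragmentary_type2,,
A17,Acarus farris,Acaroidea,Acaridae,Acarinae,False,fragmentary,interstitial,fragmentary_type2,,
A4,Acarus gracilis,Acaroidea,Acaridae,Acarinae,False,fragmentary,interstitial,fragmentary_type2,,
A1,Acarus immobilis,Acaroidea,Acaridae,Acarinae,False,fragmentary,surface,specialist,,
A10b,Acarus siro ['H'],Acaroidea,Acaridae,Acarinae,True,omnivore,surface,omnivore_type1,,
A15,Acarus siro [SW sp.],Acaroidea,Acaridae,Acarinae,True,omnivore,interstitial,specialist,,
AL2,Aleuroglyphus ovatus,Acaroidea,Acaridae,Acarinae,False,omnivore,interstitial,small_omnivore,,
C3,Sancassania berlesei,Acaroidea,Acaridae,Rhizoglyphinae,False,omnivore,surface,omnivore_type1,,
C10,Cosmoglyphus oudemansi,Acaroidea,Acaridae,Rhizoglyphinae,False,fragmentary,surface,specialist,,
C5,Cosmoglyphus hughesae,Acaroidea,Acaridae,Rhizoglyphinae,False,fragmentary,interstitial,fragmentary_type2,,
KL,Kuzinia laevis,Acaroidea,Acaridae,Acarinae,False,omnivore,surface,omnivore_type1,,
L1,Lardoglyphus konoi,Acaroidea,Lardoglyphidae,,False,fragmentary,interstitial,fragmentary_type2,,
L3,Lardoglyphus zacheri,Acaroidea,Lardoglyphidae,,False,omnivore,surface,specialist,,
LA1,Neosuidasia sp.,Acaroidea,Suidasiidae,Acarinae,False,omnivore,interstitial,small_omnivore,,
T34,Madaglyphus legendrei,Acaroidea,Acaridae,Acarinae,False,fragmentary,interstitial,fragmentary_type2,,
R2,Rhizoglyphus echinopus,Acaroidea,Acaridae,Rhizoglyphinae,True,omnivore,surface,omnivore_type1,,
R1,Rhizoglyphus echinopus,Acaroidea,Acaridae,Rhizoglyphinae,True,omnivore,surface,omnivore_type1,,
S5,Suidasia pontifica,Acaroidea,Suidasiidae,Suidasiinae,False,fragmentary,interstitial,fragmentary_type2,,
TH4,Thyreophagus sp.,Acaroidea,Acaridae,Rhizoglyphinae,False,omnivore,surface,omnivore_type1,,
TH3,Thyreophagus entomophagus,Acaroidea,Acaridae,Rhizoglyphinae,False,fragmentary,surface,specialist,,
T66,Tyroborus lini,Acaroidea,Acaridae,Acarinae,False,omnivore,surface,omnivore_type1,,
T62,Tyrolichus casei,Acaroidea,Acaridae,Acarinae,True,omnivore,surface,omnivore_type1,,
T89,Tyrophagus brevicrinatus,Acaroidea,Acaridae,Acarinae,False,fragmentary,surface,specialist,,
T40,Tyrophagus longior,Acaroidea,Acaridae,Acarinae,True,omnivore,surface,specialist,,
T6,Tyrophagus nieswanderi,Acaroidea,Acaridae,Acarinae,True,fragmentary,interstitial,fragmentary_type2,,
T17,Tyrophagus palmarum ['A'],Acaroidea,Acaridae,Acarinae,False,fragmentary,surface,specialist,,
T32,Tyrophagus palmarum ['B'],Acaroidea,Acaridae,Acarinae,False,fragmentary,interstitial,fragmentary_type2,,
T7,Tyrophagus vanheurni,Acaroidea,Acaridae,Acarinae,False,omnivore,surface,specialist,,
T8,Tyrophagus perniciosus ['A'],Acaroidea,Acaridae,Acarinae,False,omnivore,surface,specialist,,
T38,Tyrophagus perniciosus ['B'],Acaroidea,Acaridae,Acarinae,False,omnivore,surface,omnivore_type1,,
T13,Tyrophagus putrescentiae ['A'],Acaroidea,Acaridae,Acarinae,False,fragmentary,interstitial,fragmentary_type2,,
T9,Tyrophagus putrescentiae ['B'],Acaroidea,Acaridae,Acarinae,False,fragmentary,interstitial,fragmentary_type2,,
T87,Tyrophagus robertsonae,Acaroidea,Acaridae,Acarinae,False,fragmentary,interstitial,fragmentary_type2,,
T44,Tyrophagus similis ['A'],Acaroidea,Acaridae,Acarinae,False,fragmentary,interstitial,fragmentary_type2,,
T21,Tyrophagus similis ['B'],Acaroidea,Acaridae,Acarinae,False,fragmentary,surface,specialist,,
T11,Tyrophagus savasi,Acaroidea,Acaridae,Acarinae,False,fragmentary,interstitial,fragmentary_type2,,
T90,Tyrophagus tropicus,Acaroidea,Acaridae,Acarinae,False,fragmentary,interstitial,fragmentary_type2,,
Ca4,Carpoglyphus lactis,Hemisarcoptoidea,Carpoglyphidae,,False,fragmentary,interstitial,fragmentary_type2,,
CH1,Chortoglyphus arcuatus,Glycyphagoidea,Chortoglyphidae,,False,omnivore,interstitial,small_omnivore,,
G3,Glycycometus hughesae,Glycyphagoidea,Aeroglyphidae,,False,omnivore,interstitial,small_omnivore,,
G6,Lepidoglyphus destructor,Glycyphagoidea,Glycyphagidae,Glycyphaginae,True,omnivore,surface,omnivore_type1,,
G5,Glycyphagus domesticus,Glycyphagoidea,Glycyphagidae,Glycyphaginae,True,omnivore,interstitial,small_omnivore,,
D4,Dermatophagoides farinae,Pyroglyphoidea,Pyroglyphidae,Dematophagoidinae,False,omnivore,interstitial,specialist,debris durophage,
D5,Dermatophagoides microceras,Pyroglyphoidea,Pyroglyphidae,Dematophagoidinae,False,fragmentary,interstitial,fragmentary_type2,,
D3,Dermatophagoides pteronyssinus,Pyroglyphoidea,Pyroglyphidae,Dematophagoidinae,False,fragmentary,interstitial,fragmentary_type2,,
CV1(66),Winterschmidtiidae sp.,Hemisarcoptoidea,Winterschmidtiidae,,False,fragmentary,interstitial,fragmentary_type2,,
F1,Forcellinia galleriella,Acaroidea,Acaridae,Acarinae,False,fragmentary,interstitial,fragmentary_type2,,
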