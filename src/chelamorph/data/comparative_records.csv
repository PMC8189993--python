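taxon,leverage_or_VR,PHI_squared,product,gape,reach,designation,source
Achipteria coleoptrata,0.369,798.06,469.45,21.25,76.5,Primary decomposer,Perdomo et al. (2012)
Amerus troisii,0.713,3721.0,2653.23,46.0,181.0,Microphytophage,Schuster (1956)
Amerus troisii,0.299,676.0,338.0,22.0,87.0,Carnivore/Omnivore,Perdomo et al. (2012)
Arcoplophora villosa,0.5,1225.0,612.5,25.0,82.5,Fragmentary feeder,Kaneko (1988)
Austrachipteria sp.1,0.404,1764.0,1177.53,30.8,104.0,Lichenivourous,Perdomo et al. (2012)
Austrachipteria sp.2,0.433,1936.0,1201.39,31.63,101.5,Secondary decomposer,Perdomo et al. (2012)
Belba verticillipes,0.571,4761.0,2716.57,51.0,176.0,Microphytophage,Schuster (1956)
Ceratoppia sexpilosa,0.544,4761.0,2588.79,48.0,169.0,Microphytophage,Schuster (1956)
Ceratozetoidid,0.376,858.49,632.57,19.0,78.0,Secondary decomposer,Perdomo et al. (2012)
Chamobates borealis,0.42,1667.36,1013.08,26.33,97.33,Secondary decomposer,Perdomo et al. (2012)
Chamobates cuspidatus,0.396,3025.0,1932.64,36.0,139.0,Secondary decomposer,Perdomo et al. (2012)
Chamobates voigtsi,0.453,1849.0,1280.08,26.0,95.0,Secondary decomposer,Perdomo et al. (2012)
Crotonia sp.,0.405,1778.31,1042.27,35.83,104.25,Secondary decomposer,Perdomo et al. (2012)
Cultroribatula sp.,0.443,1777.47,1235.19,29.5,95.2,Primary decomposer,Perdomo et al. (2012)
Eohypochtonius magnus,0.231,625.0,144.23,32.5,95.0,Fragmentary feeder,Kaneko (1988)
Epilohmannoides esculatus,0.667,3025.0,2016.67,52.5,125.0,Macrophytophage,Kaneko (1988)
Euepicrius lootsi,0.305,1764.0,696.14,65.25,137.75,Carnivore/Omnivore (Mesostigmatid),Perdomo et al. (2012)
Eupelops sp.,0.375,2500.0,937.5,20.0,232.5,Microphytophage,Kaneko (1988)
Gamasellus sp.,0.288,882.09,254.64,53.0,103.0,Carnivore/Omnivore (Mesostigmatid),Perdomo et al. (2012)
Gymnodamaeus bicostatus,0.693,3600.0,2493.66,41.0,136.0,Microphytophage,Schuster (1956)
Hermaniella granulata,0.706,5184.0,3659.29,51.0,175.0,Macrophytophage,Schuster (1956)
Heterobelba stellifera,0.444,756.25,336.11,22.5,87.5,Microphytophage,Kaneko (1988)
Hypochthonius rufulus,0.268,361.0,152.0,19.0,71.0,Carnivore/Omnivore,Perdomo et al. (2012)
Hypodamaeus riparius,0.388,1444.0,748.74,27.0,98.0,Secondary decomposer,Perdomo et al. (2012)
Lanceoppia sp.,0.284,729.0,364.5,24.0,95.0,Carnivore/Omnivore,Perdomo et al. (2012)
Liacarus acutidens,0.757,22500.0,17027.03,92.5,300.0,Microphytophage,Kaneko (1988)
Malaconothrus talaitae,0.449,462.25,313.27,18.44,47.83,Primary decomposer,Perdomo et al. (2012)
Nothrus palustris,0.479,1156.0,770.67,24.0,71.0,Primary decomposer,Perdomo et al. (2012)
Nothrus silvestris,0.568,5625.0,3196.43,63.0,170.0,Non-specialised,Schuster (1956)
Oppiella nova,0.429,400.0,171.43,17.5,55.0,Microphytophage,Kaneko (1988)
Oribatula tibialis,0.429,729.0,592.31,16.0,63.0,Primary decomposer,Perdomo et al. (2012)
Paradamaeus clavipes,0.407,3481.0,1779.18,45.0,145.0,Secondary decomposer,Perdomo et al. (2012)
Phthiracarus sp.,0.477,3844.0,2506.96,46.0,130.0,Primary decomposer,Perdomo et al. (2012)
Platynothrus peltifer,0.52,1521.0,1244.45,22.0,75.0,Primary decomposer,Perdomo et al. (2012)
Protoribates lophotricus,0.667,6006.25,4004.17,52.5,157.5,Panphytophage,Kaneko (1988)
Pseudoceratoppia sp.,0.374,1296.0,704.62,25.75,96.25,Secondary decomposer,Perdomo et al. (2012)
Rhysotritia ardua,0.75,7225.0,5418.75,60.0,182.5,Macrophytophage,Kaneko (1988)
Rhysotritia ardua,0.75,7225.0,5418.75,60.0,182.5,Panphytophage,Kaneko (1988)
Steganacarus cf. clavigera,0.663,4900.0,3248.52,54.0,140.0,Macrophytophage,Schuster (1956)
Tectocepheus velatus,0.432,256.0,186.18,11.0,37.0,Primary decomposer,Perdomo et al. (2012)
Xenillus tegeocranus,0.741,6561.0,4860.0,54.0,202.0,Non-specialised,Schuster (1956)
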