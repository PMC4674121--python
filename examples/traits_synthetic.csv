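taxon,CBL_cm,provenance
Zygorhiza kochii,92,measured
Agorophius pygmaeus,~60,proxy
Physeter macrocephalus,500,measured
Kogia breviceps,42,measured
Kogia sima,35,measured
Aulophyseter morricei,120,measured
Orycterocetus crocodilinus,110,measured
Brygmophyseter shigensis,140,measured
Zygophyseter varolai,150,measured
Livyatan melvillei,300,measured
Acrophyseter deinodon,100,measured
Scaphokogia cochlearis,60,measured
Placoziphius duboisi,80,measured
Physeterula dubusi,100,measured
Thalassocetus antwerpiensis,~42,proxy
Praekogia cedrosensis,45,measured
Nanokogia isthmia,~45,proxy
Aprixokogia kelloggi,55,measured
Kogiopsis floridana,70,measured
Eudelphis mortezelensis,120,measured
Albicetus oxymycterus,135,measured
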