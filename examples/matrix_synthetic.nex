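[ SYNTHETIC stand-in character matrix: 21 physeteroid OTUs x 43 unordered
  characters (states 0-3, {..} polymorphism, ? missing), simulated under a
  symmetric Mk model on a random tree by parsimorph.synthetic_data.
  The real supplementary matrix of the study this emulates was published
  only as an image; these cell values are NOT that dataset. ]
#NEXUS
BEGIN DATA;
  DIMENSIONS NTAX=21 NCHAR=43;
  FORMAT DATATYPE=STANDARD GAP=- MISSING=? SYMBOLS="0123";
  MATRIX
    Kogia_sima                   ?20?030331?200313232?01?330{03}?221020100?13??
    Aulophyseter_morricei        1200031?311?00?232322?12??0?{02}121??02?0?131?
    Praekogia_cedrosensis        02000{23}?322120030303030?313??222?13320020223
    Nanokogia_isthmia            {23}200?20?3212003??03??0133310222112?1?03121{03}
    Eudelphis_mortezelensis      2200??13?11?300232?2201121??2221133302212?3
    Albicetus_oxymycterus        22000?1301102?32313220132?1?22?1?3??0{01}2??{13}3
    Livyatan_melvillei           120?00030202003?31322012331?222?1?10002?013
    Scaphokogia_cochlearis       ??000??3{02}20200123?3?21?{02}31?223001?300021013
    Placoziphius_duboisi         221003??0202?01231322012311?2220133?002?013
    Zygorhiza_kochii             120?{23}012?2?203?1333220123?1??202??0?1?21313
    Physeterula_dubusi           1212303300120??33212?01{12}31?0{03}203??0?0011313
    Thalassocetus_antwerpiensis  1213?01330?20033??322{02}??{03}?10020?23?00011?1?
    Acrophyseter_deinodon        1?02101300?203?1??32200221?0020303000001313
    Brygmophyseter_shigensis     ?20110130212223122322030333?0202330?0?21{23}02
    Zygophyseter_varolai         120000{01}3121203313231???0?313?2??331?31211?3
    Physeter_macrocephalus       120200?302?203?1223200103?0?3?0?0?00?0?23?1
    Aprixokogia_kelloggi         1202???30232??0102123?301203??01?2210?2?311
    Kogiopsis_floridana          1?0?0213023303??0012333012030?010?200023321
    Orycterocetus_crocodilinus   3?0????30?32030?03122110120333?1020??023?11
    Kogia_breviceps              1212001??2?2031?02332010?203320202000023311
    Agorophius_pygmaeus          120?001302?2032120{23}?2?12?20{03}32?2?1000032313
  ;
END;
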