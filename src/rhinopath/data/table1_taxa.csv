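taxon,mass_kg,fad_ma,lad_ma,nisp,mni,extant,formation
Hyrachyus eximius,36.3,50.5,46.2,275,116,false,Bridger
Trigonias osborni,677,37.2,33.9,115,34,false,White River
Menoceras arikarense,375,24.8,20.4,83,61,false,Harrison
Diceratherium niobrarense,1010,33.3,30.8,72,26,false,John Day
Aphelops mutilis,1840,10.3,4.9,110,53,false,Ogalla Group
Teleoceras hicksi,1660,10.3,4.9,65,29,false,Shutler/Mascall/Rattlesnake
Diceros bicornis,1080,5.3332,0,75,4,true,
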