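taxon,category,n1,n2,n3,n4,printed_ipa,printed_overall
Hyrachyus eximius,exostoses,261,127,3,0,1.35,8.80
Hyrachyus eximius,lipping,345,46,0,0,1.11,8.80
Hyrachyus eximius,texture,256,125,9,0,1.36,8.80
Hyrachyus eximius,cavitation,307,81,4,0,1.19,8.80
Hyrachyus eximius,foramen_shape,277,102,13,0,1.32,8.80
Hyrachyus eximius,foramen_size,158,292,15,0,1.40,8.80
Hyrachyus eximius,articular_surface,579,16,1,0,1.07,8.80
Trigonias osborni,exostoses,19,88,7,0,1.90,11.06
Trigonias osborni,lipping,78,34,2,0,1.33,11.06
Trigonias osborni,texture,17,81,15,1,2,11.06
Trigonias osborni,cavitation,86,17,11,0,1.34,11.06
Trigonias osborni,foramen_shape,56,50,8,0,1.58,11.06
Trigonias osborni,foramen_size,52,42,20,0,1.72,11.06
Trigonias osborni,articular_surface,95,16,3,0,1.19,11.06
Menoceras arikarense,exostoses,12,58,21,1,2.18,13.31
Menoceras arikarense,lipping,59,32,1,0,1.37,13.31
Menoceras arikarense,texture,9,59,23,1,2.16,13.31
Menoceras arikarense,cavitation,45,21,26,0,1.77,13.31
Menoceras arikarense,foramen_shape,21,43,26,2,2.01,13.31
Menoceras arikarense,foramen_size,10,26,53,3,2.51,13.31
Menoceras arikarense,articular_surface,65,21,6,0,1.31,13.31
Diceratherium niobrarense,exostoses,14,41,19,1,2.10,12.81
Diceratherium niobrarense,lipping,33,36,6,0,1.61,12.81
Diceratherium niobrarense,texture,3,45,23,4,2.38,12.81
Diceratherium niobrarense,cavitation,36,24,14,1,1.69,12.81
Diceratherium niobrarense,foramen_shape,25,33,17,0,1.85,12.81
Diceratherium niobrarense,foramen_size,26,29,20,0,1.88,12.81
Diceratherium niobrarense,articular_surface,52,20,3,0,1.31,12.81
Aphelops mutilis,exostoses,0,47,73,11,2.69,17.57
Aphelops mutilis,lipping,61,49,20,1,1.75,17.57
Aphelops mutilis,texture,10,44,53,23,2.96,17.57
Aphelops mutilis,cavitation,35,19,44,33,2.54,17.57
Aphelops mutilis,foramen_shape,3,25,81,22,2.86,17.57
Aphelops mutilis,foramen_size,0,12,74,45,3.26,17.57
Aphelops mutilis,articular_surface,73,39,10,1,1.53,17.57
Teleoceras hicksi,exostoses,12,34,31,5,2.49,14.26
Teleoceras hicksi,lipping,54,26,2,0,1.37,14.26
Teleoceras hicksi,texture,9,34,37,2,2.43,14.26
Teleoceras hicksi,cavitation,27,36,18,1,1.82,14.26
Teleoceras hicksi,foramen_shape,9,33,38,2,2.4,14.26
Teleoceras hicksi,foramen_size,9,20,46,7,2.59,14.26
Teleoceras hicksi,articular_surface,70,10,2,0,1.169,14.26
Diceros bicornis,exostoses,16,56,3,0,1.83,12.23
Diceros bicornis,lipping,47,26,2,0,1.4,12.23
Diceros bicornis,texture,9,46,14,6,2.23,12.23
Diceros bicornis,cavitation,62,13,0,0,1.17,12.23
Diceros bicornis,foramen_shape,14,37,24,0,2.13,12.23
Diceros bicornis,foramen_size,7,33,35,0,2.37,12.23
Diceros bicornis,articular_surface,68,7,0,0,1.09,12.23
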