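# vtk DataFile Version 3.0
tractsurf surface
ASCII
DATASET POLYDATA
POINTS 98 double
22.062558518878497 8.1853396196963608 23.426285423645407
22.734806601708215 8.2236998327819641 22.168151057630425
22.662213819194609 7.3423987448422281 23.484560959393466
22.574686029265898 7.5900443101773654 25.467007076707944
22.097982402818946 8.1620238010581581 25.423151937988816
22.538952576363002 8.1858868368046487 26.168716188701282
22.685490681807014 10.369837505718209 21.439980532952926
22.825559773578782 10.374483650553184 21.326056133481778
22.805413729852805 9.7867607139334485 21.455416751650933
21.278196939684385 10.292328647331585 23.323450756428365
21.042250983201008 10.228933862666842 25.302647375575106
22.439986470434643 10.277043196454064 27.356744040798347
22.425732936976885 10.306027470940863 27.354972718376825
22.438770926344276 10.307206884120006 27.36629475129789
22.843671584070371 11.283758152325484 21.434004677128335
21.26673951957817 12.50100943502335 23.275138114851895
22.856354564176588 12.58689414052794 21.629847619253933
20.869583864423429 12.417922050117703 25.226756495335181
22.423336609250885 12.508508262882687 27.234344467699625
22.434149113630017 11.172933723482023 27.312429472527171
22.674119848242427 14.891835270189299 23.304652206678853
22.768278017561986 14.897770177058257 23.210562532448009
22.289516503954932 14.841122341380871 25.194429878434885
22.56674801075571 14.859990576933608 25.564236068054992
22.760995731196815 14.981913553746278 23.307817307059516
22.600870845199541 15.155971915342612 25.194432073171161
24.248168640227306 6.1867744949904555 23.596001261191169
24.503652783371496 6.1968939421799192 23.204697169890824
24.488418672063393 6.067541273707441 23.610612614818372
24.472641997292591 6.2041625342248068 24.323533197058659
23.231312132380832 8.2415683424359045 21.514130673006544
24.631759459366165 8.2864308233558113 20.737793196471536
24.562218950902711 6.9301000976805192 21.610768318019719
24.430326830196755 6.470671963730382 25.590489900300103
24.340432313624543 8.1684773536138806 27.532706140571651
24.082535304553311 8.3209048623043529 27.513985871269959
24.33263472461919 8.3471862783869959 27.646851547224706
24.724705241725481 10.432531561776136 20.447470628648599
24.270807719950717 10.513447875848048 28.294758339571555
23.19772658149704 12.598761565935702 21.445242300203674
24.787178757748897 12.646001602561746 20.820715168418758
22.456529759684347 12.511807548248928 27.254158294900098
24.268877473835825 12.720425492317897 28.108345021633244
24.78782303243144 14.225440196321189 21.525635507731451
24.765213554349565 14.977678727540535 22.055270248307046
24.346640263538546 14.713133924758711 27.197282661901866
24.367839075633221 15.020392642165865 26.966202185833218
24.676248801244476 16.175228881861436 23.377567593951216
24.524941512571683 16.365603610406502 25.211953326035552
26.361420387133222 6.3070143043944036 23.578506432306519
26.358222582588294 6.2751553436795646 23.673223134010591
26.354013547186604 6.3134226830978371 23.889220041717952
26.47862746151446 8.3802544926685023 20.940373364813944
26.427445552122265 7.2513901957670264 21.671372125945695
26.303542704879792 6.6499815553504398 25.658317247466336
26.219906115502731 8.3681139966387867 27.607891147043233
26.212561068004195 8.5553374417424486 27.726302234130543
26.565194677648606 10.529771921129083 20.582469120495556
26.154654107697141 10.764715481346064 28.42652489763152
26.630323535776171 12.745311539936138 20.907755851207767
26.152500504401701 12.974953615803248 28.332318061671909
26.636323889935934 14.319219811230109 21.58653011504606
26.618129971707589 15.074498144702721 22.073295456974442
25.316827492147688 15.123836348433517 27.20238365523257
26.231224644539466 15.221385701781466 27.357312529943457
26.52604964339584 16.38411598285056 23.427333152064861
26.384701439690804 16.761682435001831 25.24894426707128
26.242024889620328 15.403067572906076 27.218540603568549
26.41572233830933 6.3125322382638274 23.673891290392639
27.5203592864444 8.4745634327662174 21.676930017700602
28.272634284279739 8.5858242220482204 22.818485288750125
28.238989008031041 7.9877943198268042 23.682346779918266
28.173613399585673 8.2019800972668868 25.674076238471049
26.478489720861184 8.5834235461998816 27.609517073854764
28.150372315176792 8.7288733294156913 26.268312550009629
28.295250449143168 10.713628379516269 21.65286293420499
28.350751202331981 10.72225702831169 21.713748898526923
28.079098819602908 10.85666987772643 27.573190595760845
28.075741422367166 11.002864030179882 27.621794276268552
27.957330726323541 12.886412889338828 21.61517947182038
28.393018266898647 12.949059827046554 21.976823099559372
28.073623796130775 13.219664800443715 27.630137579260982
28.34603960172727 15.2814460099431 23.382708166787012
26.591354123080528 15.261898150712176 27.238015908391116
28.090055228877908 13.793414686150838 27.392646944809734
28.169782885844736 15.404860822747228 26.160998581141108
28.341023871455896 15.364197267848715 23.466276959330155
28.220873899017427 15.919781720329128 25.323257960423973
28.664369007952956 8.6626511985304049 23.674694707050936
28.532083659920779 8.7444351559517308 25.666889312561892
29.383077861630479 10.949177750156576 23.617508354207548
29.374460833000413 11.071799899468402 25.595509590121306
28.139812276940134 11.009379631824965 27.567915615543996
29.345081367901649 13.157855782216417 23.539452415075992
29.466207713367321 13.298138059851444 25.485182918017028
28.304690625344698 13.243802424338668 27.439669920464311
28.402425258233006 15.291502789605824 23.468345719411332
28.654308074853454 15.418041357753705 25.35573311017577
POLYGONS 192 768
3 0 1 2
3 0 3 4
3 2 3 0
3 3 5 4
3 6 7 8
3 1 6 8
3 1 0 6
3 0 9 6
3 4 10 0
3 10 9 0
3 11 4 5
3 11 12 4
3 12 10 4
3 11 13 12
3 6 14 7
3 14 15 16
3 14 6 15
3 6 9 15
3 10 17 9
3 17 15 9
3 18 12 19
3 18 17 12
3 17 10 12
3 13 19 12
3 20 16 15
3 21 16 20
3 17 22 15
3 22 20 15
3 23 17 18
3 22 17 23
3 20 24 21
3 22 24 20
3 25 24 22
3 23 25 22
3 26 27 28
3 28 29 26
3 30 31 32
3 27 30 32
3 26 30 27
3 26 1 30
3 26 2 1
3 26 29 33
3 26 33 2
3 2 33 3
3 5 34 35
3 5 3 34
3 3 33 34
3 34 36 35
3 8 31 30
3 8 7 31
3 7 37 31
3 1 8 30
3 5 35 11
3 35 13 11
3 35 36 13
3 36 38 13
3 39 7 14
3 39 40 7
3 40 37 7
3 14 16 39
3 19 41 18
3 19 42 41
3 19 13 42
3 13 38 42
3 39 43 40
3 43 39 16
3 43 16 44
3 44 16 21
3 41 45 46
3 41 46 18
3 18 46 23
3 42 45 41
3 21 47 44
3 24 47 21
3 25 48 24
3 24 48 47
3 46 25 23
3 48 25 46
3 28 49 50
3 27 49 28
3 50 29 28
3 51 29 50
3 32 52 53
3 31 52 32
3 49 27 32
3 53 49 32
3 29 51 54
3 33 29 54
3 34 33 55
3 33 54 55
3 55 36 34
3 56 36 55
3 31 37 52
3 52 37 57
3 36 56 38
3 56 58 38
3 37 40 57
3 57 40 59
3 38 58 42
3 58 60 42
3 40 61 59
3 43 61 40
3 61 43 44
3 62 61 44
3 45 63 46
3 45 64 63
3 45 42 64
3 42 60 64
3 44 65 62
3 47 65 44
3 48 66 47
3 47 66 65
3 63 48 46
3 63 67 48
3 67 66 48
3 64 67 63
3 50 49 68
3 50 68 51
3 53 52 69
3 53 69 70
3 49 53 70
3 49 70 71
3 49 71 68
3 51 68 71
3 51 71 54
3 54 71 72
3 73 72 74
3 73 55 72
3 55 54 72
3 55 73 56
3 69 57 75
3 52 57 69
3 76 70 69
3 75 76 69
3 73 74 77
3 77 56 73
3 77 78 56
3 78 58 56
3 75 59 79
3 57 59 75
3 80 76 75
3 79 80 75
3 58 78 60
3 78 81 60
3 59 61 79
3 79 61 62
3 79 62 80
3 80 62 82
3 83 84 85
3 83 81 84
3 83 64 81
3 64 60 81
3 62 86 82
3 65 86 62
3 66 87 65
3 65 87 86
3 85 67 83
3 85 87 67
3 87 66 67
3 64 83 67
3 71 70 88
3 71 89 72
3 88 89 71
3 72 89 74
3 88 76 90
3 70 76 88
3 89 88 91
3 91 88 90
3 74 92 77
3 74 89 92
3 89 91 92
3 77 92 78
3 90 80 93
3 76 80 90
3 91 90 94
3 94 90 93
3 92 91 95
3 95 91 94
3 78 95 81
3 92 95 78
3 93 82 96
3 80 82 93
3 94 93 97
3 97 93 96
3 84 97 85
3 84 95 97
3 95 94 97
3 81 95 84
3 82 86 96
3 87 96 86
3 97 96 87
3 85 97 87
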