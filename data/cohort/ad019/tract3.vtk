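# vtk DataFile Version 3.0
tractsurf surface
ASCII
DATASET POLYDATA
POINTS 98 double
22.011106950418682 8.029263199313057 25.190480855994387
22.667715605602204 8.1281564331595142 23.899531569720221
22.573844140942626 7.2088909804035133 25.077951620364924
22.480548719544579 7.3418226252219192 27.023931834846231
22.028825876305291 7.8932887487760333 27.109734815103103
22.459480397801698 7.8686356178207575 27.781170116853943
22.620176388322122 10.219293109145998 23.339012196683267
22.748890488473677 10.230133842780731 23.206926336504864
22.737265032652527 9.663608018580744 23.313879237975041
21.336522616336303 10.023285580639651 25.392520152422808
21.099993942371047 9.833911007730805 27.35196176008381
22.429587656854135 9.757804004761482 29.181845635741897
22.416481934006057 9.7847400746121203 29.184757558586419
22.429366099730899 9.7851553221493273 29.194274427160622
22.748293300291238 11.072072218124626 23.336146274039283
21.366629137920839 12.042162392599728 25.442172056819594
22.727048323475504 12.266259062687336 23.523362929648282
21.014534413645439 11.812869546288672 27.447605336913632
22.449157904918742 11.771143469535502 29.252252888678068
22.440783884507045 10.568937859509123 29.228908003519969
22.542921320803899 14.16702737275334 25.229408840182227
22.620483830878047 14.183489969231946 25.115456167772525
22.266324969276521 13.927308725777326 27.275454165202145
22.521600705111112 13.911919826829161 27.627135595566813
22.614790427311192 14.247090357874406 25.215963387307529
22.53382370410749 14.200633679662245 27.232500447755012
24.143035702695183 6.0454170238647542 24.884081421969977
24.405094765315724 6.0656095488151287 24.48966907685892
24.386800459649017 5.9217382128149509 24.861096468847617
24.365428696990637 6.0165768871183509 25.559961623493795
23.154447217001632 8.1756672784218196 23.209462560663514
24.537610837140679 8.2267181127348685 22.313304884266003
24.48185442375226 6.8606534512610402 23.044386566609891
24.327564552557877 6.2134260677446882 26.804997752550936
24.289540468731555 7.7318473900728684 28.884735397789022
24.028215368035561 7.8869565473935594 28.915081834448642
24.287531114855682 7.8945495262438037 29.016807289851329
24.542933695211282 10.31242523057362 22.096644147554198
24.272649125942745 9.8747232910363252 29.894419472054818
23.02604887540241 12.291981440995883 23.283490135231023
24.467859372543391 12.383243378656873 22.415861838048311
22.480873312190209 11.772782096104308 29.26818770298539
24.258986848313722 11.882353998780014 29.910232066785316
24.380454957480637 13.783620353321306 23.063043320207719
24.33474066707155 14.41128200922005 23.583840298742839
24.24530296755302 13.678829150416593 29.098059805671085
24.243085289224879 13.957450520699375 28.868406902982851
24.262162738244097 15.319992829675781 24.961629339992903
24.23432835802102 15.259100556521069 26.992419356596734
26.303942791880324 6.0675344141748617 24.68843048941007
26.300868898163614 6.0322007409745666 24.775100556431013
26.29556694483928 6.0562709586197414 24.985015465643443
26.397711361916567 8.2247033122914814 22.331174198625551
26.372131763396926 7.0864459042313577 22.958553994539205
26.257373001288652 6.2817019093074293 26.708305780228226
26.23270484618169 7.7881639390689692 28.768223989862815
26.230955243938009 7.9560683315013563 28.902980595708094
26.37041281139539 10.325434277225838 22.028708920440025
26.203800386249753 9.9601552294368965 29.817001218942799
26.262695172634576 12.42141069646463 22.28454316991013
26.156407375723433 11.9871229900684 29.924333814912416
26.153631581230684 13.839120824533973 22.900805772285771
26.098127545023019 14.487627040903265 23.374954857865006
25.171811905882358 14.014746617592857 29.009996311974017
26.084488729260151 14.06257836488663 29.070685997874371
26.009774989963464 15.515231835511075 24.791270896200071
26.002474956230863 15.615515017869201 26.819254292299203
26.077180747265746 14.232845046800701 28.933240877092373
26.35992440813731 6.0645396752474774 24.774425400607928
27.464979726663785 8.1959934180941119 22.93860165923531
28.250659752267463 8.1491743266598249 23.963811454736771
28.238252164426815 7.5205640581696436 24.752616662543982
28.209205089585549 7.5784743371487089 26.683527851220667
26.502878494174972 7.9646164199965135 28.764343954347474
28.200846651000941 8.0227159019274374 27.304283521599462
28.163649360174016 10.28498286011679 22.904962941373153
28.222674412401741 10.282084929312965 22.959511975952843
28.163989191449527 9.8890736113004607 28.765556033718727
28.160586035912718 10.020403526588995 28.826269955378873
27.639121713491576 12.401480525624827 22.873890662047611
28.107290167491435 12.384022145464662 23.202644313690669
28.087728261165832 12.062046289454601 29.022895639524286
27.944510095912435 14.422260478065825 24.627483647391557
26.436209467544362 14.085247603001475 28.912840485390625
28.06172202876914 12.606465473590195 28.827391893379346
27.967915312021049 14.196310423728015 27.635346237754675
27.939004404502739 14.489336238671607 24.716000522801295
27.923817355477048 14.768317391807072 26.740509375370969
28.672722780479543 8.1154998245241465 24.748717915679052
28.582430131185415 8.0433879357529037 26.684813729174213
29.357948158438084 10.185478904790799 24.74174316899137
29.42518230519774 10.094251279597565 26.70192509722833
28.224763798675621 10.022459577341891 28.766909187823082
29.185202218106411 12.285827860231523 24.727206940208909
29.419090604958143 12.165837344881417 26.717317104408991
28.316164050983783 12.07144898716407 28.809054339380697
28.009656531707769 14.415697736586635 24.71541912965569
28.413652875236771 14.261076380206632 26.732703493814704
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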