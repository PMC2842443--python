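# vtk DataFile Version 3.0
tractsurf surface
ASCII
DATASET POLYDATA
POINTS 98 double
21.459130916514422 8.3151625278344348 24.10127029535494
22.179079032568264 8.4165752042349791 22.721583240242495
22.109002060290123 7.4845244419721695 24.054184711822373
22.028146670487327 7.6169751076551 26.115963204245435
21.518358045849233 8.1923473462571561 26.146238284341702
22.001666435156647 8.1622285302288322 26.864606475169989
22.113330943524705 10.473049932079682 22.094816396271675
22.261726237777125 10.481374332999861 21.957879212259574
22.24259462072725 9.9312183065819983 22.060696920882165
20.635919425783541 10.32770455830727 24.208927051444405
20.426945145076679 10.214632561891037 26.239006014825595
21.95682511177192 10.136496628875928 28.1629860184024
21.942443933039829 10.16532968531981 28.163891553323992
21.956497442780076 10.165242926406771 28.173813372674136
22.278034596878548 11.299841956478177 22.134724375724737
20.676721811160977 12.365528791337988 24.29653880081699
22.29981025678979 12.461651872033602 22.416865901868348
20.316081543853432 12.275630850843658 26.301616245385169
21.976770993285211 12.259071780079008 28.14714883596805
21.962897374985754 10.99059804528909 28.165382618605872
22.174359032064061 14.460513819617207 24.300147518857393
22.268085347166579 14.462765472119063 24.192393418639583
21.825254932689116 14.423753756013241 26.263979908681605
22.112486141751241 14.424564119574059 26.60528973338527
22.264176712997742 14.536024230345916 24.296668567399426
22.143641757988188 14.688721465675318 26.243950370210591
23.825114134555633 6.2882950991952375 23.980738219870052
24.09935514982995 6.3120750657363542 23.55506028133841
24.084379589156114 6.1583969193577719 23.972894191147862
24.06147874981442 6.2411823285192627 24.723306616664299
22.716395229949555 8.4701717743029512 21.974630633551854
24.219181271564057 8.5090264617385039 21.013696552067049
24.163464097479636 7.14701117367387 21.892770753357929
24.019354139783974 6.4238861852806366 26.034829493907946
23.946883866836384 7.9600278673813492 28.06339319604103
23.673184125398468 8.1282990530502897 28.074965119340423
23.941609191957713 8.1263829084065424 28.183781257782375
24.276963799736738 10.506085655271564 20.812401937167149
23.8986948982777 10.170335930192756 28.901595002791918
22.652904725484902 12.468584805515691 22.182623780694886
24.31056247218276 12.455614544500678 21.329750315550399
22.011374475107623 12.259419180253461 28.163229246705388
23.888983307088804 12.27406769917987 28.789425176683466
24.308775652973978 13.807426774439056 22.150742998505621
24.293683372433783 14.444262662949832 22.738637878424701
23.935197676676129 14.147840170538903 27.974044742730193
23.950885377649595 14.429754918255977 27.760797900446583
24.228674756461292 15.45948198637713 24.161056256352776
24.090490336297201 15.625512795452426 26.065751714752903
26.074119481312561 6.2522912235855577 23.83996397949932
26.071007372338652 6.2155225001453349 23.936775459078305
26.064597367875667 6.2363288118436486 24.162835472574173
26.184795902993883 8.4096860293831401 21.121258341910686
26.143719692440559 7.2941914021556675 21.864826633161179
26.009802488199171 6.4438957570605098 25.982561707897304
25.9326923661718 7.9590129064502992 27.980607452195777
25.926121419892478 8.1292959265401237 28.101989501084002
26.235759495813156 10.396199161916833 20.81965003226458
25.860562554410858 10.176041741913533 28.834243129600196
26.259665467328386 12.344077755819026 21.249821077543519
25.814417943205459 12.271591183373213 28.776754714848906
26.245650449357502 13.694491265575866 22.01602956619675
26.22406228002087 14.339473091532085 22.544011947300884
24.90586261168583 14.422841428231292 27.861908014245657
25.82659289661262 14.403673279300707 27.882081874182305
26.135429093928757 15.461768161333286 23.9751027356977
25.980017852123233 15.79797580382823 25.848801672791684
25.833387183893667 14.572853597666606 27.752935307347542
26.131494081950635 6.2458561340185055 23.936041330152641
27.290851718820054 8.306728757427754 21.866912264876614
28.087900314948001 8.2174636562966743 23.036606614983736
28.055240071685727 7.612050573971282 23.908693561459209
27.983944359139425 7.6851101996979034 25.924848926395491
26.203692565423701 8.1307208642464808 27.966679323939669
27.956430014904019 8.133962306936489 26.526916591118646
28.086670012047588 10.230386636786347 21.876363241241297
28.1460721761717 10.224802410805356 21.938172130147159
27.860255723641515 10.026168506894098 27.831295109627451
27.854045160486493 10.159633903490905 27.879133470025746
27.677866197985171 12.228734264602267 21.910691199419002
28.144540300112407 12.191454514273886 22.262571216665112
27.782103768368895 12.229741976841007 27.898980365432557
28.042336541336081 14.223852773748641 23.735187771432436
26.189595254541011 14.392384407790976 27.723024799879958
27.775767517594819 12.77465791523753 27.676398189282637
27.812182049161631 14.301239139218943 26.504942000659831
28.035037573020222 14.296800794188346 23.820404822721859
27.870073970648253 14.783567030886649 25.686169725319395
28.50420668600049 8.1728665568136449 23.898146913611395
28.360836490575174 8.1348372835656519 25.907271071651781
29.245856300582265 10.129573497719955 23.855328120648561
29.224562318172225 10.12428528829259 25.822174603117265
27.920828655105122 10.158488217073897 27.822019135312068
29.154505848275704 12.126960086489865 23.809498741980313
29.257906412943814 12.145018742252566 25.725536409467605
28.021748875994078 12.220523870638994 27.696149548900216
28.100889470246226 14.221187462138312 23.817124137343171
28.331632571004114 14.24943958868052 25.672695845112148
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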