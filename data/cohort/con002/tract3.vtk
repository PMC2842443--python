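# vtk DataFile Version 3.0
tractsurf surface
ASCII
DATASET POLYDATA
POINTS 98 double
21.2319070669121 7.530524703773767 24.660042897721862
21.962563904213383 7.7077195868429387 23.400282067975517
21.899219090313938 6.7550811414843173 24.603939010885995
21.877825023357207 6.8240445555725504 26.418252746412843
21.358462212063188 7.3446767379606026 26.444875686327137
21.894574577396426 7.3362709467444907 27.071269491220278
21.957245317189916 9.7975432111072074 22.690272107102743
22.112878353068524 9.8177636753157973 22.552771272504831
22.069144173093729 9.2516840653435395 22.704272574036974
20.444146868937299 9.4958861299370536 24.68680555858905
20.301911305087021 9.270207451388174 26.468187067524994
22.007199389858464 9.2573536166103807 28.178981402740408
21.993896406108028 9.2846885808056872 28.178505959834915
22.009295507179345 9.2858132160987505 28.187822083734808
22.178618489315745 10.662140249451836 22.610490162982135
20.616893466220905 11.572114994417392 24.555371965866819
22.280246512920012 11.860681223069578 22.698644552458195
20.326269694990152 11.350763401509974 26.375262333611406
22.190127405960926 11.404475769648441 28.072452626995897
22.075567547750161 10.119442052449708 28.149076174729622
22.351825745550791 13.832893687904226 24.196693434016449
22.446702285877471 13.849140862540484 24.087644295690883
22.08697639218229 13.666931623678833 26.111839582760823
22.416376134118288 13.679156852560853 26.445334427169119
22.452375820147591 13.918241716721255 24.178849084395758
22.445656466922994 13.965862184407991 26.065679366802826
23.691231889023832 5.7167385802729536 24.455638109169872
23.972286247175042 5.7642274893559629 24.056654862103994
23.96219509018465 5.6109022972443672 24.434970356160406
23.955385678249179 5.6869996165855801 25.116155241852024
22.519950049862665 7.8002349528347761 22.692720290259125
24.104009010725623 7.9475360468130054 21.694827276413552
24.024517141599834 6.5842827522498091 22.545029067244428
23.945391642557816 5.8463768966982901 26.310447836795358
23.986588356262612 7.3170304148983565 28.16809216446519
23.706009690324873 7.4523451855595493 28.173296174098205
23.993849734566737 7.4789365116183646 28.278552403360486
24.243426282549034 10.014180038732711 21.322746663796888
24.115278528366115 9.4985858883848984 28.929713408764304
22.651045313860891 11.90338626240773 22.449640799499708
24.398566763955824 12.068906233410598 21.519620027312538
22.22811402300281 11.407943513878958 28.088705966022864
24.287530457687982 11.616060936689333 28.7850794692073
24.503146154583867 13.470972097806168 22.093009914564604
24.548210525569605 14.109851939416556 22.577190743438898
24.464177602242554 13.535725932030809 27.911456939869392
24.491479233270152 13.829305192337188 27.681265126887322
24.612039094926391 15.072919654985153 23.883217751197254
24.608127902276856 15.123147672088585 25.846107100845039
26.052861772879659 5.8825095618428938 24.218307486305477
26.050531409866817 5.8458010482415848 24.308453106977115
26.049054803115691 5.8669076640780879 24.51932352276102
26.182322265303963 8.0501010945875322 21.641293815998242
26.116168333154299 6.9168932043042179 22.372458146655728
26.038256149858672 6.0620490596510681 26.224217671904952
26.086140232029251 7.5397670446471494 28.123101763789219
26.093925271477719 7.7072610218934647 28.240093459255021
26.318226664690798 10.130854340016349 21.201962320955982
26.215383010482419 9.7385948777612281 28.960483078156898
26.465574468073093 12.203781676841261 21.373903245931071
26.379852853283754 11.842317616953469 28.91508178705994
26.563273005807371 13.613619976501957 21.947794768001696
26.606072389728027 14.265031763148258 22.398880988043846
25.549615763114698 13.929468239007909 27.865745598942048
26.567822295938278 14.018766781540641 27.976004355604825
26.672800207644869 15.333212098329371 23.760300798570555
26.686633736178315 15.540778018883174 25.739177713254374
26.582750417137301 14.194925683162481 27.835951011584854
26.114742164304058 5.8817231498951204 24.305267031359083
27.358230605689144 8.0822001950902127 22.277619771183613
28.224097683738165 8.0839336154272754 23.362729610523044
28.18415947149979 7.4521546647151906 24.208554147926403
28.172877099323618 7.5005683431982266 26.155479954849561
26.383935318102662 7.7409188411965886 28.116034610058385
28.19309281736847 7.9453318463409088 26.744935994466694
28.297826256918928 10.20364544957541 22.160795611680005
28.362622527471054 10.205016295541805 22.220278514035847
28.304251148694494 9.8295661144618336 28.057213187249129
28.313386748433132 9.9630540994069126 28.107576167892983
27.995284618443748 12.27408003240622 22.034391026723892
28.50864901961285 12.291537120168909 22.398740978093862
28.474689600309365 12.056962683349301 28.167314513443877
28.652720027711403 14.34676204319492 23.756803233748379
26.95823551441547 14.059199337339338 27.845358665801029
28.521916204297128 12.618947285779619 27.945507606973635
28.652504355084968 14.233331520612493 26.705069605934511
28.657526906155351 14.416330967224672 23.841472849315288
28.688970998176814 14.779346859083933 25.809198901124823
28.686069005969134 8.0758238398658282 24.184762545318623
28.599332355264806 7.994920761253173 26.141774464755127
29.607399569349205 10.201260141879045 24.114190829844901
29.68294339589519 10.130552566872193 26.087385891410182
28.382485677137836 9.9703887571448444 28.053219495572332
29.684112681472723 12.298843704240735 24.01481668396076
29.933038597360273 12.235695575193189 26.004925581716151
28.723472568428697 12.08270402376194 27.974621383313401
28.723283124526418 14.347531737768445 23.84850581118566
29.146680650694005 14.296168962420483 25.856846919193398
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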