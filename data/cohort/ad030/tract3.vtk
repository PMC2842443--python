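# vtk DataFile Version 3.0
tractsurf surface
ASCII
DATASET POLYDATA
POINTS 98 double
22.724779030499846 8.9859133964418554 24.505192441350658
23.395470567100425 8.8280380198984112 23.170871095509312
23.234313379209045 8.0898883388402645 24.479195816408076
23.181620144650221 8.5307620197591802 26.527799727597081
22.769541872623297 9.1729119072937806 26.546917662743308
23.214942862645753 9.1949178432563521 27.287619917477397
23.592645671801453 10.774892112388777 22.500649060898642
23.729478488942075 10.758321225151199 22.37217400118395
23.641333808630609 10.233834616211832 22.493421640407274
22.203049065498355 11.041469375474749 24.539621095732713
21.974513453715041 11.288230510547441 26.582758586600061
23.373368970575292 11.335632499881916 28.628034514251834
23.363063855101473 11.365509412865599 28.62840247876424
23.376033706958967 11.36495823070698 28.639333039410726
23.862107200587609 11.585150253341125 22.509568361530835
22.497802479478814 12.97800588182908 24.544643647717471
24.035746427883449 12.743689762203894 22.72670557128647
22.107383731801477 13.241473827924608 26.586859193284983
23.651375373091149 13.361361565563499 28.612936904121298
23.484842035930178 12.165583098471377 28.637287639400171
24.167589440928118 14.899381188202478 24.525580830264573
24.256020255449162 14.886655664709856 24.420338613461091
23.816272266409449 15.140132817555491 26.555605607808072
24.087837368177016 15.175595160052056 26.939125881753952
24.260003602409022 14.969313356566101 24.52398860184784
24.151501480761102 15.37200671142071 26.546409896017234
24.714378669175844 6.7395701600716116 24.422272477740929
24.970803607810101 6.6985279529635484 24.007835279875859
24.944551767343992 6.5893162532142284 24.413711795778585
24.942405902932386 6.7663514148016581 25.157303395278515
23.886780280424098 8.7438651559269687 22.458065941834501
25.272454965403529 8.6149302333494369 21.56150535507096
25.085605390490972 7.3428695262853161 22.404038969830527
24.922606228923293 7.1021928894301425 26.465415263049785
24.997689594975327 8.8990059533945889 28.557614357845992
24.759045992986373 9.1057196912292522 28.567395273244429
25.008897250052378 9.0807792573417281 28.685662678792468
25.570173046547563 10.608798463276928 21.324543376513308
25.197800414783082 11.205532702746245 29.491207283781399
24.361404078437268 12.716749142822563 22.510826402864478
25.857312317423325 12.615005791163039 21.742264637794666
23.684177639194225 13.360370013872567 28.632271607411941
25.473762165815963 13.24164075122102 29.429543298585465
26.032624424709471 14.034309533355554 22.493948831837727
26.101664922838175 14.717624837072458 23.061812715913877
25.792180037091885 14.950020004344026 28.574320871877706
25.846403090241459 15.198036128389202 28.342731067181255
26.176261809859593 15.845748585256038 24.490341305904384
26.10863490541205 16.184502114385868 26.494858403176462
26.83866633845917 6.5873091346555022 24.292940131315458
26.83289326550382 6.5579532466755488 24.387278290821666
26.832403693518557 6.6009045471323979 24.612095691840519
27.104928144615332 8.5339276872841374 21.673580898979615
26.970824814808051 7.4654009524560436 22.382124690022454
26.808536551739788 6.9695353824113653 26.433895377050501
26.882733653048479 8.6742870086320885 28.521063559645096
26.894465684117193 8.8561097106143514 28.653199982377856
27.359970736332535 10.541559881519913 21.36590092743004
27.082492153640377 10.966091341847545 29.511927134771394
27.60966042162821 12.56323801946203 21.737379746199657
27.347153589524694 13.024506157648196 29.554703733886363
27.76822857695926 13.982490098291665 22.467211877242452
27.835100143272502 14.664077965942209 22.990480251078299
26.778158493859976 15.131101030167253 28.549973011776959
27.680191689497285 15.042842271782476 28.663859710125635
27.929856606282048 15.868667096033375 24.459884157370528
27.924260069966881 16.299362729425148 26.457405980196668
27.708589933063408 15.200078345006233 28.526469369231371
26.89340769122753 6.5872625435766601 24.38748716602008
28.150105204134032 8.5114452355139676 22.391979607168608
28.918499006966407 8.5076100142821147 23.542196831698504
28.845416444084758 7.937888825592772 24.39582266127443
28.811001580942516 8.1217980723602103 26.434746254125578
27.162038257196652 8.8221626418356678 28.521042529008252
28.839714583682568 8.6087739461323416 27.071317330414082
29.081196505903655 10.506729727482982 22.416459438965553
29.137738195393236 10.506004107504518 22.478281968494901
28.997758042627471 10.566626269749607 28.525277797080239
29.011102739684969 10.701266696069123 28.583504691710658
28.914110451616672 12.549583658870823 22.443628906878303
29.352636129723713 12.543648433434697 22.813853366220361
29.26175584501982 12.756995054489392 28.736327165029589
29.562296734670163 14.656353820412241 24.35539551129331
28.033892994074421 14.999769851492958 28.526847725345775
29.338911556414033 13.291714181908896 28.531917680849102
29.555305113430752 14.783963346725718 27.336569476117781
29.569451630583512 14.731775441283009 24.446213070929936
29.616268292198669 15.252041066730644 26.457708219549868
29.322869759542911 8.5032141818536928 24.401294785669506
29.217798266728224 8.5589467237382983 26.438974815007295
30.222245892440736 10.494083066787764 24.424854339328476
30.275625853440292 10.527077157115428 26.460783192137384
29.075009591295451 10.692526564722307 28.5255594046507
30.363026269817045 12.534712113123133 24.441901850185562
30.579571737919839 12.558704768220062 26.471786504139857
29.489099863800757 12.723903481991227 28.531170274415445
29.622398170078348 14.656251638281912 24.446150731148588
29.988570233417356 14.705431031159119 26.463069665619617
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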