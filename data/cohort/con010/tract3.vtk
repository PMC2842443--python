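# vtk DataFile Version 3.0
tractsurf surface
ASCII
DATASET POLYDATA
POINTS 98 double
20.962032872475664 7.8914302830107843 24.890376648696954
21.654684517779472 7.8875350046359944 23.486002395756525
21.655840089700096 7.1137338137946466 24.864879594842023
21.643158696582759 7.4160912647617545 27.053872632104891
21.115351482268959 7.9563905332322173 27.063990454784886
21.648690933610172 7.9978182223701664 27.872084292203045
21.4635440086277 9.7839596543624765 22.813296889589203
21.613495711192524 9.7886962856303121 22.67819387443587
21.626434777244466 9.2742557803750163 22.794972533512365
20.04252180595816 9.7733815088213341 24.939145956309012
19.971664229474154 9.8417771535337888 27.081234313255905
21.731972505547983 9.9628658040490627 29.321920823458321
21.717828241025295 9.9894170436810317 29.321924161392065
21.733625093684175 9.9904631030942816 29.33422634908009
21.586821709995544 10.568736752258911 22.84180741270891
19.993349895994772 11.647380457957736 24.982332403943236
21.553103227478779 11.663138648686575 23.096111259151272
19.816590356875054 11.720012521391052 27.104900127954441
21.804760336888865 11.883929491953555 29.325377012944141
21.758810851233221 10.744063698382849 29.33906062135722
21.443484841034437 13.521644518771986 25.022395595117583
21.531478786678452 13.521414837602361 24.912193391994915
21.330274308381654 13.597777278295013 27.160893639285185
21.69310319358387 13.626914307014147 27.575810844886444
21.534468914089608 13.589297191939641 25.022347177862901
21.660814981387741 13.826616295894679 27.16346903869961
23.454201300585652 6.013168414997371 24.810687215506348
23.730539745518371 6.0135169657840502 24.367722338930612
23.725086648215669 5.8964106111819481 24.80092483466316
23.70925704048792 6.0311600332366639 25.600836913707401
22.19387774851484 7.8987415145694158 22.733332066837164
23.749565081137185 7.9537922992369641 21.780577069694761
23.754556583401918 6.6963019366363481 22.661959218460659
23.693916717436839 6.3035380291674361 27.010587353372806
23.730212555046919 7.9317720072481039 29.282591582198368
23.452145718423626 8.0905418921599423 29.291241032142747
23.73888040246797 8.100162550961187 29.422157150786013
23.709851920076833 9.8803416012128178 21.559888287839627
23.866460228426057 10.086447735039105 30.30559665098145
21.91295541902895 11.675733440193152 22.868233717035629
23.648642337102263 11.760813439304648 22.037015248913114
21.844236483760611 11.886249911478323 29.347478941543908
23.977329642154874 11.994786445688259 30.250563009637194
23.601317022547839 13.017056676413882 22.849931056888593
23.584578107478787 13.58714141666381 23.455430831962257
23.956240763984848 13.559929280301066 29.343148102186646
23.934963893121793 13.782259874158591 29.096880791368061
23.598524904688915 14.474138958427483 24.976247070163573
23.739209992238312 14.67252422406083 27.124615912720387
25.781172274029981 6.0605401163921755 24.656286734293513
25.779609439341911 6.0299710545691507 24.757024571195469
25.774341117027873 6.0624784230990478 24.998336346008259
25.824357783390987 8.037264477633288 21.876386074401889
25.81776410133077 6.9744676690290879 22.622576640725025
25.747742600611708 6.3630498550385717 26.95865846992967
25.78731437191465 7.9400628512406044 29.221082455787233
25.796524879300264 8.1108813601677205 29.364618374934214
25.803885905656539 9.987072883178044 21.56566568606825
25.930739055695749 10.099788227253496 30.296981984567832
25.754975747668304 11.880970806688557 21.973877526893805
26.054366402029853 12.026983505822479 30.340463892638947
25.708566530216856 13.132386145210866 22.74893354589091
25.688949312537304 13.703574640917722 23.30077046015257
25.016799931512072 13.823629087277766 29.297795724110461
26.040477323565508 13.851891611334397 29.3739917364455
25.68844956073519 14.655192701748664 24.85481585418367
25.8107182668404 14.947133741241661 26.995710332636463
26.027666864419853 13.989617232363591 29.225598067425995
25.841914456576589 6.0622565344167887 24.756257986572464
27.001015289824089 8.0738496624461042 22.607849895760804
27.858115495861078 8.0826579603791675 23.789718277433593
27.842177044690924 7.5006431649597012 24.696896974801287
27.818707343571006 7.6165623729371781 26.87012170660697
26.075804804676398 8.1054412132939806 29.211513530389137
27.824050780457497 8.067103072477904 27.549423735808571
27.806358288045079 10.062794212501741 22.597300066674109
27.871213775551787 10.063926990781045 22.658859720589991
27.906358450853062 9.9149947410604522 29.095143667073646
27.913935526495184 10.042816131648907 29.156473190109509
27.31573040860766 11.952891545512159 22.643319439683598
27.835616963307654 11.9693389205594 22.999361727689728
27.997174463270682 11.972284307932734 29.296611520404422
27.789751950778097 13.793594292931857 24.598375481855388
26.402302953054427 13.846748749678897 29.199762327289978
27.996272040630426 12.462310170326218 29.068956377568249
27.922626866376298 13.808691209059507 27.766148157722942
27.789767233814448 13.855670727183689 24.693321658155522
27.861616848033279 14.236979510615958 26.822282547494282
28.314483190213306 8.0796150356527807 24.673065670799723
28.22264494419057 8.0635774743584498 26.843888244503418
29.102847775257239 10.050371569228021 24.618877402660228
29.182773623873675 10.012965809018757 26.757517857663931
27.978043177886832 10.040312042825555 29.087940846238006
29.008316920222473 11.967520824348195 24.61088317211571
29.279464159630592 11.933136526683681 26.720522967372911
28.219019656545253 11.962252754406613 29.050188154681354
27.862119969441082 13.795337207259406 24.68779579709549
28.348086177545596 13.800827011437356 26.781407205173728
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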