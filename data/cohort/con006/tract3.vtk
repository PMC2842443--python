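# vtk DataFile Version 3.0
tractsurf surface
ASCII
DATASET POLYDATA
POINTS 98 double
21.614076015679984 8.2164506573578215 24.073641490685866
22.233936124431374 8.2089697838722628 22.825149793665723
22.232853857088834 7.3645717914665463 24.069042861827754
22.313380523732608 7.6436349610774981 25.996985348992592
21.839450423282255 8.2316485792076488 25.991904510810866
22.372292187562326 8.2404990411792998 26.697196792206459
22.165507824762994 10.257343001895162 22.218087050593223
22.305989261667929 10.254665346519145 22.098968905613248
22.283277992279331 9.7018953990821029 22.200352383996364
20.853835091377938 10.275474958608235 24.109241773672736
20.850603481209973 10.288049564621611 26.00087287900266
22.536132955031974 10.278428265527364 27.927097526896997
22.523522544272975 10.307097197028279 27.927083473554323
22.538116919272465 10.307183517166299 27.937655869584013
22.347536075861925 11.08660629761826 22.251019708994548
20.929318093325069 12.295235382992573 24.171619595809382
22.40809047319182 12.247570541211111 22.498591944994086
20.786920904698764 12.315730099860154 26.04680084580982
22.626807205725161 12.307088133647987 27.945448691870972
22.574907777165105 11.104281293440526 27.940252939332442
22.45193341337858 14.163259873508013 24.258520069047172
22.538630587284484 14.156866860148471 24.162272079514686
22.293628944560197 14.205129221009457 26.130235273797833
22.624071421699309 14.193593419708114 26.491188367178502
22.544382806624842 14.224455664390199 24.262048329931584
22.617216684296583 14.412678757896559 26.142769526675252
23.900125425214775 6.1533266929516044 24.082742587140284
24.150968557705792 6.1488076190730476 23.693944455552074
24.154237087994517 6.0248672748621903 24.08614536173916
24.173535162626408 6.1593078063325564 24.793698903086394
22.727763518972321 8.2046376508409118 22.159103909009751
24.189208438431216 8.1802721242574794 21.336356211792953
24.150939696921714 6.8657671871527848 22.145699646282687
24.2152374287502 6.4299762029341148 26.03407684269294
24.353162971231349 8.0903091663699591 27.963728495213967
24.096302574731094 8.2606325176748463 27.956841018819834
24.365925027708485 8.2624531339479574 28.07961786178997
24.276839625672554 10.19837297115833 21.141109320457062
24.495594255760821 10.29679900439613 28.80266538698654
22.750412463856573 12.233538918310048 22.300198436546381
24.389107195259886 12.1588997136269 21.603091147111279
22.662556679704394 12.306386942851587 27.964290282348912
24.58996903700881 12.255165911264681 28.771033076655755
24.479869899394146 13.446132889508396 22.369547354055602
24.526555145968917 14.018260930304629 22.931358261560323
24.643377593098872 13.870985946712235 28.052450909319955
24.648860054217977 14.101976951925755 27.852770310894634
24.608630498431438 14.884315322746298 24.318768403034259
24.657118513753705 15.040063171149294 26.204688481697385
26.130742290933174 6.1427416439940732 24.045547566857401
26.13108332799511 6.1121581258774347 24.137014547595104
26.135503605773874 6.1466131940305928 24.352504248500541
26.172786645965967 8.1351779450774089 21.508721004269368
26.138636567762646 7.0593517245804414 22.19254198299663
26.178797909596327 6.4617192309679714 26.090738159529149
26.296384562799126 8.0723592233019552 28.025783981556692
26.308041900599118 8.2457245207171468 28.145823098891128
26.264712881598708 10.117562035322054 21.238932161621914
26.433003700666614 10.248922406212799 28.919287660404969
26.388590808846942 12.039980055867799 21.651078058745558
26.542897253213894 12.163300451237475 28.979877834541192
26.494146737771558 13.294838409780258 22.396493569938809
26.549676217809182 13.858792897274794 22.918684183364707
25.664220428677588 14.03127229237885 28.085024721952781
26.644363218452945 13.959799466781167 28.23372677982319
26.655116820669054 14.777637457550389 24.356377091915981
26.70447253432728 15.040529861016973 26.254550776204841
26.65229011950677 14.095110695224843 28.114929660733335
26.192174377533195 6.1437512560642977 24.139383765328855
27.319832369321738 8.1136727089692933 22.254633852251231
28.178163949054692 8.1090667155356382 23.412186416302582
28.163333854697541 7.5519289054837024 24.235183621382234
28.200968364252397 7.7157079737444549 26.180922290836111
26.574119577512285 8.2387867166678284 28.036633598429709
28.234359951897702 8.1791048955903847 26.776869102231203
28.206254735573225 10.040968757183627 22.339853173268111
28.270409007722439 10.038816623271806 22.402972281726264
28.364083461954625 10.033251974783294 28.120823868869699
28.372825043834197 10.159148039724313 28.174587545347414
27.901366989167297 11.94082296039176 22.386862340571945
28.411705149214484 11.909846549915837 22.766415596563249
28.50359973916278 12.023492784269251 28.333231238698673
28.603617767698854 13.686504583152647 24.295494204044967
27.017784524066663 13.921546588029457 28.123620449128385
28.538414371626359 12.486806658686964 28.156155591419385
28.642293553905823 13.739569207077249 27.097556815484658
28.611151623742003 13.746452144010338 24.384098055452323
28.674715123650632 14.129336778007517 26.2970449532699
28.640487787527373 8.1162507742098331 24.267079046139852
28.604357734725674 8.1593945650998432 26.204926930117274
29.511752322694374 10.016467902057069 24.347906088802507
29.622667882783258 10.056210921199911 26.282010648106361
28.436530095831543 10.155193209119076 28.124997783837387
29.586192722693344 11.851435682192092 24.386499262436548
29.855939160532422 11.875997898867674 26.3168811451472
28.735972702489761 12.002695666652194 28.1577757253255
28.674582289955666 13.681378703128095 24.384877968878815
29.114237266540048 13.677765168803631 26.306798711818402
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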