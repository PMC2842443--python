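# vtk DataFile Version 3.0
tractsurf surface
ASCII
DATASET POLYDATA
POINTS 98 double
22.61810698549009 7.3606605179242974 24.189402429812304
23.379320923767747 7.4272173669036956 22.779747774353776
23.160207656125188 6.6137825567812421 24.14401133077634
22.941065445670809 6.864565039586469 26.184228145682155
22.502804535665028 7.3849913309750876 26.216944834387782
22.887736184264238 7.4299675863405117 26.91421111633279
23.433237263607584 9.377841816081034 22.025043279131829
23.576670575550121 9.3939252700493387 21.878923231683306
23.544546920675579 8.8575009834592233 22.024398851306159
21.923686208948403 9.2256218396834964 24.228559968240543
21.551446517441562 9.253414616011554 26.269075146860196
22.797900049591803 9.3986865507392281 28.170417653588657
22.78476557945914 9.4256337028149577 28.170921422858413
22.796945491733595 9.4268659258535035 28.180792565306657
23.569572554293689 10.204931936297882 21.98917003834606
21.89086307115825 11.204847048946833 24.171299308190438
23.517861216561545 11.374112070339242 22.173670742537738
21.388085472593446 11.224396183329308 26.228018479786098
22.777156673417206 11.413953114394209 28.113000275293885
22.797652410338561 10.20780122641875 28.158334930430211
23.062014652257819 13.380504524035647 23.964017120916079
23.156694118192235 13.389255079925835 23.84859283393769
22.602511318365398 13.36824858201531 26.049890607094319
22.849189770427103 13.396691208253664 26.417010128749659
23.136322005379743 13.462685397802872 23.95292249618922
22.872752779133044 13.641562963004857 26.016133599690324
24.638168398308174 5.5752722313104677 24.017723178803262
24.91552507249008 5.5903093535794692 23.578936722052124
24.865508337567032 5.4657416794009093 23.998671263628104
24.803341552450124 5.578884408964691 24.742950139382501
23.918417323863778 7.4834153637451726 22.006057098082866
25.329853956004708 7.5892821980653729 20.955826266059326
25.137522306032828 6.3111683635428752 21.899837331029609
24.696086080373281 5.8215408020277168 26.047078363645866
24.579869510971953 7.3992015851330271 28.060958084299696
24.333785551460199 7.5496814646554178 28.078128723454991
24.573800005667447 7.565072781242109 28.181332842859778
25.464455762975867 9.562989347996643 20.604916671351326
24.53471271046417 9.5557081997492457 28.912309198660196
23.855165188788572 11.410847169900579 21.916637280959108
25.426552495307053 11.561888766809609 20.959091866291889
22.808040866759615 11.416715257167786 28.129980363291203
24.514913253687485 11.548321961436129 28.815877397817221
25.27381645194161 12.945503895155758 21.697134929424262
25.155786273414023 13.580852259080403 22.269615448805318
24.521413289612141 13.288471864592845 27.955665325270719
24.528083562537887 13.548986828693291 27.722851248784973
24.884974949875488 14.554360878777457 23.737721304684996
24.63446949344274 14.672979329772073 25.831107522875563
26.694388242482603 5.6446097069286374 23.735269477517061
26.68398713925934 5.613784815448037 23.833907018300728
26.666399642443473 5.6427002952864269 24.060268051176774
27.088210198492717 7.6316451805738312 20.907017583750903
26.938620356763675 6.5672173735642101 21.71298220130581
26.527526823164674 5.921785596411925 25.893949073399849
26.4142763979257 7.4679826980420039 27.919162089897487
26.407635073466601 7.63725005813696 28.044477222873702
27.236271623329507 9.6220563000605228 20.462894650822715
26.35758445460672 9.6349882539464655 28.835293110062633
27.234920624182571 11.645921069191052 20.759800326739885
26.326382619432291 11.638469005670046 28.846863775573151
27.115983478494179 13.040900067372881 21.481287899804464
27.018285568033097 13.689040100758659 22.016421242199851
25.440791024042081 13.604381089847783 27.880766831578526
26.332051917237909 13.651941417702895 27.950725874091905
26.753196808792634 14.759267384430391 23.554002781803799
26.48309484324486 15.009664914340517 25.673102402162545
26.337008524583794 13.811957982017692 27.812020578655194
26.741202950849505 5.6455084136553806 23.827899209319721
28.0429498668001 7.6293293817480441 21.556828920412997
28.697285055454827 7.6290827039551941 22.678720525718777
28.585456685215256 7.0625789929636804 23.604880466894965
28.412043525753052 7.2032203773536176 25.696159893480583
26.671428386740352 7.6423385466096079 27.896056415903097
28.372150213929132 7.6598749446266616 26.320873465814508
28.864615254839538 9.6250673019854851 21.381217337264985
28.915341536066322 9.624996474605366 21.43997235305223
28.273496465784977 9.5430344287072515 27.730485359927727
28.268530845149371 9.674311657692602 27.786464637682414
28.519939454063781 11.658945632724642 21.351074336298193
28.936760713805612 11.661397021145051 21.692305872611872
28.232672926134995 11.688194322022557 27.906508482512603
28.711868396949594 13.721319834951521 23.283264004710674
26.689848684426035 13.664189023192487 27.789123381685233
28.239767470038721 12.214610397000671 27.691376969112561
28.321536633930105 13.709208129717195 26.449753878706034
28.697120901065826 13.792256742670729 23.380102357825365
28.410084217642215 14.207183165749841 25.528519449938301
29.029223868141571 7.6381513805218999 23.53711479341322
28.781529032757785 7.6588152173057686 25.648137054395789
29.808416849721883 9.6384648089884379 23.372585913602734
29.664682192451718 9.6645351388837089 25.500802810724167
28.333957938188703 9.6747719876659115 27.723139193548796
29.785432979237015 11.671025443440644 23.307175973369706
29.755204427454295 11.689819339070159 25.442022553223413
28.470082579361637 11.691065021722858 27.680067288768534
28.763885662617955 13.721971044430383 23.374316737523202
28.873824590509685 13.721495526055296 25.493585490731309
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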