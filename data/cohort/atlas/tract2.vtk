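# vtk DataFile Version 3.0
tractsurf surface
ASCII
DATASET POLYDATA
POINTS 140 double
5.7289290428161621 8 10
6 8 9.3843698501586914
6 7.6542835235595703 10
6 7.4709734916687012 12
5.5892119407653809 8 12
6 8 13.129383087158203
5.8257155418395996 10 8
6 10 7.773404598236084
6 9.5592527389526367 8
5.0026512145996094 10 10
4.9563474655151367 10 12
6 9.1162681579589844 14
5.741447925567627 10 14
6 10 14.320279121398926
5.8213648796081543 12 8
6 12 7.7690219879150391
5.0502123832702637 12 10
5.139439582824707 12 12
6 12 13.816493034362793
6 11.465082168579102 14
6 12.454874992370605 8
5.849449634552002 14 10
6 14 9.5987548828125
6 14 11.356046676635742
6 13.856204986572266 12
6 14.187793731689453 10
7.9121417999267578 6 12
8 6 11.037930488586426
8 5.9535412788391113 12
8 6 12.148680686950684
6.839597225189209 8 8
8 8 6.991875171661377
8 7.0254697799682617 8
8 6.0571517944335938 10
8 6.754817008972168 14
6.4541058540344238 8 14
8 8 15.208714485168457
8 10 6.062716007232666
8 10 15.818988800048828
8 12 6.1096267700195312
6.1256475448608398 12 14
8 12 15.446358680725098
6.8520474433898926 14 8
8 14 7.0714101791381836
6.0916142463684082 14 12
7.699613094329834 14 14
8 14 14.225544929504395
8 14.901559829711914 8
8 15.741432189941406 10
8 15.493851661682129 12
8 14.226791381835938 14
8.2129125595092773 6 10
10 6 8.8376865386962891
10 5.5980415344238281 10
10 5.576754093170166 12
10 6 13.226471900939941
10 8 6.2739162445068359
10 6.3600287437438965 8
10 6.340057373046875 14
10 8 15.600778579711914
8.1895256042480469 10 6
10 10 5.4996452331542969
10 8.6108856201171875 6
10 9.2212505340576172 16
8.8544092178344727 10 16
10 10 16.216951370239258
8.380192756652832 12 6
10 12 5.5948801040649414
9.886103630065918 12 16
10 12 16.028528213500977
10 12.951198577880859 6
10 14 6.5481657981872559
10 12.068487167358398 16
10 14 15.010339736938477
10 15.350119590759277 8
9.3695764541625977 16 10
10 16 9.6736812591552734
10 16 11.766737937927246
10 15.985504150390625 12
10 14.987009048461914 14
10 16.10368537902832 10
12 6 9.5283660888671875
12 5.8483395576477051 10
12 5.9040894508361816 12
12 6 12.257126808166504
12 8 6.518211841583252
12 6.611295223236084 8
12 6.8602285385131836 14
12 8 15.098549842834473
12 10 5.7005362510681152
12 9.1536445617675781 6
11.572536468505859 10 16
12 10 15.935585975646973
12 12 5.8406352996826172
10.842559814453125 12 16
12 12 15.960787773132324
12 12.347873687744141 6
12 14 6.992621898651123
12 14 15.082313537597656
12 14.88758659362793 8
10.617011070251465 16 10
12 15.74349308013916 10
12 15.79603385925293 12
12 15.014503479003906 14
12.339091300964355 6 10
12.205105781555176 6 12
14 8 7.8732309341430664
14 7.8823304176330566 8
14 6.9828543663024902 10
14 7.1275558471679688 12
13.596927642822266 8 14
14 8 13.498373985290527
12.644596099853516 10 6
14 10 6.8443336486816406
14 8.5207061767578125 14
14 10 14.817328453063965
12.337828636169434 12 6
14 12 7.0567712783813477
14 12 15.055034637451172
13.411825180053711 14 8
14 13.372462272644043 8
14 14 8.7660760879516602
14 14 14.10344123840332
14 14.610197067260742 10
14 14.84677791595459 12
14 14.093883514404297 14
14.109606742858887 8 8
14.944841384887695 8 10
14.805920600891113 8 12
15.005815505981445 10 8
15.76885986328125 10 10
15.710664749145508 10 12
14.781447410583496 10 14
14.826377868652344 12 8
15.685272216796875 12 10
15.776254653930664 12 12
15.010940551757812 12 14
14.628584861755371 14 10
14.877761840820312 14 12
14.098132133483887 14 14
POLYGONS 276 1104
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
3 14 7 6
3 15 7 14
3 9 16 6
3 16 14 6
3 10 17 9
3 17 16 9
3 18 12 19
3 18 17 12
3 17 10 12
3 13 19 12
3 14 20 15
3 20 21 22
3 20 14 21
3 14 16 21
3 23 17 24
3 23 21 17
3 21 16 17
3 18 24 17
3 21 25 22
3 23 25 21
3 26 27 28
3 28 29 26
3 30 31 32
3 30 2 1
3 30 32 2
3 32 33 2
3 27 26 3
3 27 3 33
3 33 3 2
3 5 34 35
3 3 34 5
3 3 29 34
3 3 26 29
3 34 36 35
3 8 31 30
3 8 7 31
3 7 37 31
3 1 8 30
3 5 35 11
3 35 13 11
3 35 36 13
3 36 38 13
3 7 15 37
3 37 15 39
3 19 40 18
3 19 41 40
3 19 13 41
3 13 38 41
3 42 15 20
3 42 43 15
3 43 39 15
3 20 22 42
3 24 44 23
3 24 18 40
3 24 40 44
3 44 40 45
3 46 40 41
3 45 40 46
3 42 47 43
3 22 47 42
3 22 25 47
3 25 48 47
3 44 25 23
3 44 49 25
3 49 48 25
3 45 49 44
3 50 49 45
3 46 50 45
3 51 52 53
3 51 28 27
3 51 53 28
3 53 54 28
3 54 29 28
3 55 29 54
3 32 56 57
3 31 56 32
3 52 51 33
3 52 33 57
3 57 33 32
3 27 33 51
3 29 55 58
3 34 29 58
3 58 36 34
3 59 36 58
3 60 61 62
3 60 62 56
3 60 56 37
3 37 56 31
3 63 64 38
3 63 38 59
3 59 38 36
3 63 65 64
3 66 61 60
3 67 61 66
3 37 39 66
3 60 37 66
3 64 68 41
3 38 64 41
3 69 64 65
3 68 64 69
3 66 70 67
3 70 66 39
3 70 39 71
3 71 39 43
3 68 72 73
3 68 73 41
3 41 73 46
3 69 72 68
3 43 74 71
3 47 74 43
3 75 76 74
3 75 74 48
3 48 74 47
3 77 75 48
3 77 48 78
3 78 48 49
3 50 79 49
3 49 79 78
3 73 50 46
3 79 50 73
3 75 80 76
3 77 80 75
3 53 81 82
3 52 81 53
3 54 53 83
3 53 82 83
3 83 55 54
3 84 55 83
3 57 85 86
3 56 85 57
3 81 52 57
3 86 81 57
3 55 84 87
3 58 55 87
3 87 59 58
3 88 59 87
3 62 89 90
3 61 89 62
3 85 56 62
3 90 85 62
3 91 63 59
3 91 59 92
3 92 59 88
3 63 91 65
3 61 67 89
3 89 67 93
3 94 91 92
3 95 94 92
3 65 94 69
3 91 94 65
3 67 96 93
3 70 96 67
3 96 70 71
3 97 96 71
3 72 94 95
3 72 95 73
3 73 95 98
3 69 94 72
3 71 99 97
3 74 99 71
3 76 100 101
3 76 101 74
3 74 101 99
3 100 77 78
3 100 78 101
3 101 78 102
3 79 103 78
3 78 103 102
3 98 79 73
3 103 79 98
3 76 80 100
3 77 100 80
3 82 81 104
3 82 105 83
3 104 105 82
3 83 105 84
3 86 106 107
3 85 106 86
3 104 81 86
3 104 86 108
3 108 86 107
3 105 104 108
3 109 105 108
3 110 109 111
3 87 109 110
3 87 105 109
3 87 84 105
3 87 110 88
3 90 89 112
3 90 112 113
3 90 113 85
3 85 113 106
3 110 111 114
3 114 88 110
3 114 115 88
3 115 92 88
3 112 93 116
3 89 93 112
3 117 113 112
3 116 117 112
3 92 115 95
3 115 118 95
3 93 96 116
3 97 119 120
3 96 97 120
3 96 120 117
3 96 117 116
3 120 119 121
3 95 118 98
3 118 122 98
3 97 99 119
3 119 123 121
3 119 99 123
3 99 101 123
3 102 124 101
3 101 124 123
3 103 125 102
3 102 125 124
3 122 103 98
3 125 103 122
3 107 106 126
3 107 127 108
3 126 127 107
3 108 128 109
3 127 128 108
3 109 128 111
3 126 113 129
3 106 113 126
3 127 126 130
3 130 126 129
3 128 127 131
3 131 127 130
3 111 132 114
3 111 128 132
3 128 131 132
3 114 132 115
3 129 117 133
3 113 117 129
3 130 129 134
3 134 129 133
3 131 130 135
3 135 130 134
3 132 131 136
3 136 131 135
3 115 136 118
3 132 136 115
3 117 120 133
3 121 133 120
3 121 137 133
3 137 134 133
3 135 134 138
3 138 134 137
3 136 135 139
3 139 135 138
3 118 139 122
3 136 139 118
3 121 123 137
3 124 137 123
3 138 137 124
3 125 138 124
3 139 138 125
3 122 139 125
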