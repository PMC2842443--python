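# vtk DataFile Version 3.0
tractsurf surface
ASCII
DATASET POLYDATA
POINTS 118 double
19.820680618286133 26 26
20 26 24.289592742919922
20 24.711410522460938 26
20 26 26.818464279174805
20 26.376646041870117 26
21.890464782714844 22 24
22 22 23.74809455871582
22 21.92584228515625 24
22 21.93341064453125 26
21.900119781494141 22 26
22 22 26.226276397705078
21.002729415893555 24 22
22 24 20.827232360839844
22 22.822288513183594 22
20.179861068725586 24 24
20.109176635742188 24 26
22 22.752494812011719 28
20.805191040039062 24 28
22 24 29.406436920166016
20.96711540222168 26 22
22 26 20.829887390136719
20.033063888549805 26 24
20.301765441894531 26 28
22 25.972810745239258 30
21.991611480712891 26 30
22 26 30.00648307800293
22 27.212139129638672 22
21.50514030456543 28 24
22 28 23.195518493652344
20.995285034179688 28 26
21.443855285644531 28 28
22 28 28.715246200561523
22 26.0146484375 30
22 28.32655143737793 24
22 28.707513809204102 26
22 28.403553009033203 28
23.228593826293945 22 22
24 22 21.465963363647461
24 21.676652908325195 22
24 21.014768600463867 24
24 21.050937652587891 26
24 21.747407913208008 28
23.347795486450195 22 28
24 22 28.426540374755859
23.43928337097168 24 20
24 24 19.751245498657227
24 23.628200531005859 20
24 23.561868667602539 30
23.165708541870117 24 30
24 24 30.325042724609375
23.519865036010742 26 20
24 26 19.792823791503906
24 26 30.666854858398438
24 26.284936904907227 20
23.475393295288086 28 22
24 28 21.7073974609375
24 27.573631286621094 30
24 28 29.77294921875
24 28.170490264892578 22
24 29.006282806396484 24
24 29.419036865234375 26
24 29.141056060791016 28
26 22 21.219907760620117
26 21.475229263305664 22
26 20.720121383666992 24
26 20.782146453857422 26
26 21.609798431396484 28
26 22 28.595014572143555
26 24 19.748069763183594
26 23.596124649047852 20
26 23.660219192504883 30
26 24 30.230949401855469
26 26 19.81785774230957
26 26 30.411842346191406
26 26.247833251953125 20
26 28 21.792617797851562
26 26.913202285766602 30
26 28 29.397722244262695
26 28.118511199951172 22
26 28.919500350952148 24
26 29.294887542724609 26
26 28.933761596679688 28
27.471803665161133 22 22
28 22 22.470327377319336
28 21.372806549072266 24
28 21.444459915161133 26
27.101484298706055 22 28
28 22 27.260099411010742
26.567888259887695 24 20
28 24 20.808443069458008
28 22.392293930053711 22
28 22.616313934326172 28
26.49406623840332 24 30
28 24 29.108465194702148
26.398172378540039 26 20
28 26 20.959661483764648
26.779062271118164 26 30
28 26 29.133432388305664
26.316854476928711 28 22
28 27.001890182495117 22
28 28 23.938760757446289
27.532550811767578 28 28
28 27.417463302612305 28
28 28 26.811908721923828
28 28.020854949951172 24
28 28.206378936767578 26
28.771503448486328 22 24
28.693740844726562 22 26
29.005495071411133 24 22
29.786064147949219 24 24
29.762399673461914 24 26
28.936416625976562 24 28
28.857654571533203 26 22
29.643285751342773 26 24
29.648902893066406 26 26
28.898500442504883 26 28
28.028865814208984 28 24
28.255788803100586 28 26
POLYGONS 232 928
3 0 1 2
3 2 3 0
3 0 4 1
3 3 4 0
3 5 6 7
3 5 8 9
3 7 8 5
3 8 10 9
3 11 12 13
3 6 11 13
3 6 5 11
3 5 14 11
3 9 15 5
3 15 14 5
3 16 9 10
3 16 17 9
3 17 15 9
3 16 18 17
3 19 12 11
3 20 12 19
3 14 21 11
3 21 19 11
3 2 1 21
3 2 21 15
3 15 21 14
3 3 2 15
3 3 15 22
3 22 15 17
3 23 17 18
3 23 24 17
3 24 22 17
3 23 25 24
3 19 26 20
3 26 27 28
3 26 19 27
3 19 21 27
3 1 4 29
3 1 29 21
3 21 29 27
3 4 3 22
3 4 22 29
3 29 22 30
3 31 24 32
3 31 30 24
3 30 22 24
3 25 32 24
3 27 33 28
3 29 33 27
3 34 33 29
3 30 34 29
3 35 34 30
3 31 35 30
3 36 37 38
3 36 7 6
3 36 38 7
3 38 39 7
3 8 7 40
3 7 39 40
3 10 41 42
3 10 8 41
3 8 40 41
3 41 43 42
3 44 45 46
3 37 44 46
3 36 44 37
3 36 12 44
3 36 13 12
3 6 13 36
3 10 42 16
3 18 47 48
3 16 47 18
3 16 43 47
3 16 42 43
3 47 49 48
3 50 45 44
3 51 45 50
3 12 20 50
3 44 12 50
3 18 48 23
3 48 25 23
3 48 49 25
3 49 52 25
3 50 53 51
3 54 55 53
3 26 54 53
3 26 53 50
3 26 50 20
3 26 28 54
3 32 56 57
3 31 32 57
3 52 32 25
3 56 32 52
3 54 58 55
3 28 58 54
3 28 33 58
3 33 59 58
3 34 60 33
3 33 60 59
3 35 61 34
3 34 61 60
3 57 35 31
3 61 35 57
3 38 62 63
3 37 62 38
3 39 38 64
3 38 63 64
3 40 39 65
3 39 64 65
3 41 40 66
3 40 65 66
3 66 43 41
3 67 43 66
3 46 68 69
3 45 68 46
3 62 37 46
3 69 62 46
3 43 67 70
3 47 43 70
3 70 49 47
3 71 49 70
3 45 51 68
3 68 51 72
3 49 71 52
3 71 73 52
3 51 74 72
3 53 74 51
3 74 53 55
3 75 74 55
3 56 76 77
3 57 56 77
3 73 56 52
3 76 56 73
3 55 78 75
3 58 78 55
3 59 79 58
3 58 79 78
3 60 80 59
3 59 80 79
3 61 81 60
3 60 81 80
3 77 61 57
3 81 61 77
3 63 62 82
3 83 63 82
3 83 84 63
3 84 64 63
3 65 64 85
3 64 84 85
3 86 85 87
3 86 66 85
3 66 65 85
3 66 86 67
3 69 68 88
3 69 88 89
3 62 69 89
3 62 89 90
3 62 90 82
3 83 82 90
3 86 87 91
3 92 91 93
3 70 91 92
3 70 86 91
3 70 67 86
3 70 92 71
3 88 72 94
3 68 72 88
3 95 89 88
3 94 95 88
3 96 92 93
3 97 96 93
3 71 96 73
3 92 96 71
3 72 74 94
3 75 98 99
3 74 75 99
3 74 99 95
3 74 95 94
3 99 98 100
3 101 102 103
3 97 102 101
3 96 97 101
3 96 101 77
3 96 77 76
3 73 96 76
3 75 78 98
3 98 104 100
3 98 78 104
3 78 79 104
3 80 105 79
3 79 105 104
3 103 81 101
3 103 105 81
3 105 80 81
3 77 101 81
3 84 83 106
3 84 107 85
3 106 107 84
3 85 107 87
3 90 89 108
3 90 106 83
3 90 108 106
3 108 109 106
3 107 106 110
3 110 106 109
3 87 111 91
3 87 107 111
3 107 110 111
3 91 111 93
3 108 95 112
3 89 95 108
3 109 108 113
3 113 108 112
3 110 109 114
3 114 109 113
3 111 110 115
3 115 110 114
3 93 115 97
3 111 115 93
3 95 99 112
3 100 112 99
3 100 116 112
3 116 113 112
3 114 113 117
3 117 113 116
3 102 117 103
3 102 115 117
3 115 114 117
3 97 115 102
3 100 104 116
3 105 116 104
3 117 116 105
3 103 117 105
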