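# vtk DataFile Version 3.0
tractsurf surface
ASCII
DATASET POLYDATA
POINTS 98 double
21.335880279541016 8 24
22 8 22.694126129150391
22 7.1747946739196777 24
22 7.4284896850585938 26
21.485504150390625 8 26
22 8 26.726503372192383
21.856101989746094 10 22
22 10 21.874404907226562
22 9.4573593139648438 22
20.47273063659668 10 24
20.368415832519531 10 26
22 9.9719076156616211 28
21.985368728637695 10 28
22 10 28.01078987121582
22 10.828761100769043 22
20.461740493774414 12 24
22 12 22.211980819702148
20.214176177978516 12 26
22 12 27.980924606323242
22 10.792622566223145 28
21.910776138305664 14 24
22 14 23.896236419677734
21.681510925292969 14 26
22 14 26.378646850585938
22 14.071449279785156 24
22 14.241557121276855 26
23.737939834594727 6 24
24 6 23.596193313598633
24 5.8747882843017578 24
24 6 24.723569869995117
22.512447357177734 8 22
24 8 21.136125564575195
24 6.7096290588378906 22
24 6.2468619346618652 26
24 7.8337373733520508 28
23.725883483886719 8 28
24 8 28.120811462402344
24 10 20.86168098449707
24 10 28.866838455200195
22.34698486328125 12 22
24 12 21.256031036376953
22.036184310913086 12 28
24 12 28.801948547363281
24 13.370611190795898 22
24 14 22.56620979309082
24 13.740560531616211 28
24 14 27.781360626220703
24 14.96722412109375 24
24 15.104727745056152 26
26 6 23.905971527099609
26 5.9684491157531738 24
26 6 24.219152450561523
26 8 21.274759292602539
26 6.9258313179016113 22
26 6.281771183013916 26
26 7.8306999206542969 28
26 8 28.124908447265625
26 10 20.930953979492188
26 10 28.924224853515625
26 12 21.278404235839844
26 12 28.961105346679688
26 13.365677833557129 22
26 14 22.522705078125
25.018373489379883 14 28
26 14 28.129596710205078
26 15.057278633117676 24
26 15.326107025146484 26
26 14.15819263458252 28
26.060781478881836 6 24
27.148599624633789 8 22
28 8 23.145416259765625
28 7.4207954406738281 24
28 7.5449275970458984 26
26.276113510131836 8 28
28 8 26.611690521240234
27.936473846435547 10 22
28 10 22.062021255493164
28 9.869898796081543 28
28 10 28.055498123168945
27.497507095336914 12 22
28 12 22.374683380126953
28 12 28.197006225585938
28 14 23.908891677856445
26.374637603759766 14 28
28 12.523639678955078 28
28 14 26.852611541748047
28 14.068931579589844 24
28 14.482616424560547 26
28.45533561706543 8 24
28.386869430541992 8 26
29.218732833862305 10 24
29.300321578979492 10 26
28.065759658813477 10 28
29.144136428833008 12 24
29.386144638061523 12 26
28.236740112304688 12 28
28.068525314331055 14 24
28.47589111328125 14 26
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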