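# vtk DataFile Version 3.0
tractsurf surface
ASCII
DATASET POLYDATA
POINTS 98 double
20.622583599456298 8.6586358987780496 24.256145412204802
21.391501138489559 8.6999949701285413 22.924134660526963
21.330211602949788 7.7337401246571815 24.254747949067735
21.157205611714197 7.8250136065746325 26.266477457406101
20.604280937666196 8.4659354202184129 26.25555726809262
21.06351377942562 8.3466101070478604 26.984692805805096
21.26197411292917 10.866200077762388 22.189909686342666
21.414055228037927 10.861598589761289 22.057646013903629
21.408686220525773 10.285430603813198 22.198407327714918
19.72272341563087 10.827070856314995 24.217320448136498
19.439272859936938 10.639264207134675 26.177552180789355
20.888570163112952 10.235113884320812 28.180035317126112
20.873477544664905 10.265447396675453 28.17822062089369
20.887385612537305 10.262622812765917 28.18925504943671
21.40019352335981 11.72417700832618 22.163654105587248
19.747232611721572 12.898129126554908 24.118136105985673
21.395063516019448 12.917446566982218 22.325618130475775
19.330286133570436 12.714372107206284 26.05260758892841
20.912719231581136 12.327777013087875 28.038802475876096
20.88544633247718 11.086251923655217 28.140280358920116
21.208622506189307 14.815602704412038 23.965638268673146
21.301289589432969 14.817251563145653 23.863300567382211
20.835581460331056 14.636321153397587 25.919891509367687
21.112736480110637 14.566544418439308 26.297784146030672
21.295888527993228 14.87924970078363 23.95874743332201
21.152690818830184 14.850099301877526 25.902011288358654
23.174474744896429 6.3491726542953879 24.23570728888302
23.465999137195404 6.3554421404401591 23.818022765986246
23.452522213300767 6.1940956591615599 24.232423694251366
23.402489709994043 6.2721323651785204 24.977528852424403
21.955645812161819 8.6968107028140764 22.19794128331197
23.495579682804269 8.6183566697630596 21.253826215543594
23.507758622831922 7.2039271611565701 22.162163989711466
23.304700374876116 6.4164543856201135 26.277943299598927
23.048648520338478 7.8358327599394331 28.284653482554237
22.748445793770152 8.033845042999312 28.278337022772227
23.029287824840679 7.9914439025864077 28.402956604787995
23.454491915128376 10.73875538300311 20.93776974390634
22.890367235787846 9.9434618020453041 29.09128719909511
21.74762262587247 12.901554012238472 22.102346047983474
23.401800789278564 12.785127045674239 21.279470136004658
20.947256814730444 12.321763311664247 28.058914620120724
22.892405276599803 11.999479593972863 28.914885452824418
23.341294781408727 14.132121036528092 21.965831432364507
23.299171163037865 14.726774999077435 22.495727236469921
22.980730992597426 13.883343915949135 27.969539012814934
22.999013626224475 14.175604900157795 27.726002160083876
23.20900920249283 15.576015517502602 23.851620758041058
23.107214345290881 15.508511712850396 25.832559305662141
25.521420080508282 6.1415352534493151 24.127003632714647
25.520089972028273 6.101226414110597 24.224606433806631
25.509845324205706 6.1167801672045057 24.452975357085062
25.495736972956099 8.4256702808097206 21.34053444221848
25.528533844186075 7.2499215634870708 22.122695662837856
25.413800631059587 6.2519592467657956 26.289101779284735
25.19946650959567 7.6244897120549089 28.312874871944032
25.181683391994149 7.7820714392046728 28.436456375529669
25.422146938696965 10.53513861364558 20.930618975102583
25.041486885709695 9.7151776050990311 29.186726702493907
25.337866108079091 12.568298250823171 21.217848715333695
25.006333386242581 11.743672087350244 29.113056720591832
25.258695802385922 13.903060373667982 21.888841286699556
25.213628247557065 14.50221364344748 22.381133853871024
24.02426907300001 14.025023834367047 27.961806166497642
25.037980629762828 13.886656581166163 28.100343173136654
25.122901130560734 15.434514044252486 23.795875298046628
25.069235937177186 15.492497122063146 25.796652430216977
25.041366511524092 14.064090436933316 27.952901466564043
25.581460004281094 6.1276762456938965 24.224682274529137
26.644519745964036 8.2471266715528451 22.088723551392356
27.505000519965609 8.0421419375959111 23.299483105959958
27.527198829251819 7.3662422315084255 24.214829782689975
27.473896363233429 7.3025786756367097 26.298081572847511
25.489781978966455 7.7656368363466326 28.314486853544555
27.427678744146348 7.7039707179419255 26.920356595488368
27.339555588241151 10.220677347434028 22.010475342984634
27.403419144101644 10.206816956133908 22.075378582330654
27.282213607470922 9.4534893836203562 28.278958770326462
27.274662687462772 9.5793175185338058 28.329451148441219
26.787136677294487 12.330851444826878 21.920449244189665
27.283596094234571 12.231359814821369 22.300198599389855
27.195754195833498 11.595900614574065 28.35145902925402
27.144715663117658 14.120924292198689 23.746908350654145
25.429399348854442 13.858126022038958 27.971186799025507
27.181452690674277 12.152510660624854 28.108589322309612
27.134581153269103 13.795177341659237 26.790452975332901
27.140139592363312 14.18170462941654 23.834845056570234
27.113892961415033 14.386104963954361 25.859997434101285
27.972082005873883 7.9008628784658752 24.203057702381194
27.863071465476267 7.7144219560575378 26.293113903084365
28.652613326821086 9.8464076579389381 24.123750230144886
28.729706210268056 9.6248964526136334 26.223918008799114
27.348579723340258 9.5771614153323359 28.273522696978606
28.442562996608054 11.909938007904611 23.991334580376478
28.702616685742509 11.65936521118741 26.084990485529421
27.455761882205056 11.588980120749447 28.150653697946069
27.213106180752497 14.10252244438402 23.839556009085037
27.629249396915867 13.831469904679448 25.904041591225713
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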