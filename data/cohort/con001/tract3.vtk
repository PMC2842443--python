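# vtk DataFile Version 3.0
tractsurf surface
ASCII
DATASET POLYDATA
POINTS 98 double
21.267620015578064 7.7819242083169486 24.066042972744611
22.013341014075575 7.8309157092834232 22.722422532529169
21.973021549010237 6.9511031302240109 24.056810274487987
21.884124478957034 7.0422821921650511 26.126320525670561
21.326671749340221 7.6056194489541973 26.138707006219967
21.831517844700368 7.5172855352756907 26.891061848429661
21.888805819685256 9.8503652684684866 22.01359840338726
22.0450593948216 9.8475744054961485 21.884139488339184
22.039281809467223 9.3025627597462801 22.013146069047288
20.356972555273636 9.8107929739394439 24.07165100406694
20.128560343149282 9.6066630042375447 26.162656095670886
21.695289401564562 9.2423208753646655 28.257176348264082
21.678878992266462 9.269485238635415 28.257884912359312
21.69381225719237 9.2676702061579093 28.268931571271647
22.040781570406661 10.671070598367359 22.007992069410719
20.336731967305973 11.829714472581079 24.071125893104536
22.026177917647093 11.839139632035597 22.222172072624836
19.955389645763297 11.613563946745433 26.173117684295061
21.665248803145612 11.202772201278828 28.24737065900247
21.6803534639132 10.028596633510448 28.262440028093742
21.8097680354029 13.744189992627216 24.066440614111386
21.908703470571144 13.74686967351094 23.957970930425979
21.451479607547828 13.517510050688953 26.157667118493357
21.761185601030132 13.437612597474976 26.548688689326799
21.901369701814911 13.809768639554658 24.06593533762431
21.781164788922268 13.738263403149633 26.151881545610028
23.833906159032914 5.7825893678809068 24.018827150575817
24.12253306902068 5.799972080359332 23.599207116275881
24.116349407820938 5.6606152325637034 24.011609949248978
24.105440392819077 5.7446945633040896 24.751424372982889
22.574611983426689 7.8400552482547941 22.009681191437206
24.176061015111767 7.8256937550754335 21.095499670873409
24.147288250111728 6.5449991277894783 21.976133464182098
24.074731012339672 5.9001214724756101 26.065917664418578
23.969275940062744 7.2252562388785151 28.156697883170956
23.654469436577752 7.3763500873712431 28.171474857375003
23.958947602938526 7.3684963024883841 28.284672440148579
24.204247428529492 9.7966715159466577 20.805106483689752
23.865003659991277 9.1563918104780022 29.082038933504709
22.401245063216862 11.826643969601475 22.00081670522902
24.192429356833269 11.771664854188632 21.199523230816364
21.70260215800899 11.198468706805158 28.266406292568107
23.828903390102351 11.061014033451327 29.014965705069105
24.142865772712334 13.116325626520556 21.964308113896255
24.102483638118692 13.71932208442052 22.550315030926011
23.849327743331912 12.862003628620874 28.168898690474773
23.856484336469943 13.148534681442998 27.940398196709818
24.005924456386712 14.583518978369684 24.037675162710737
23.91323366992097 14.494098608271752 26.099156651368549
26.305698374789639 5.8050036551469564 23.836897315917223
26.305900293704834 5.7708302246659917 23.93307071188207
26.308737827951035 5.7926017002823391 24.155780602633079
26.327572534935765 7.817667758409276 21.139155502482097
26.307551764526778 6.7595260134141348 21.889323982664941
26.321257231517627 5.9721589253677543 25.974199692821827
26.303549697334088 7.2910739794064785 28.026811447545022
26.299523599532201 7.4391536341856135 28.155488178452341
26.362673114442241 9.7740548402254674 20.764779002199433
26.248901092096727 9.237682704217324 28.977191000797724
26.364885591110014 11.73044601712672 21.111003761911082
26.205592986118969 11.122200260776944 29.009199551545287
26.331442599264101 13.056254815523738 21.862787555356892
26.302701494648058 13.66055017438376 22.412003931203653
25.017414306975507 13.123817334507109 28.10162008433425
26.178221276808923 13.139549525503082 28.158258469563162
26.227915559315694 14.609436420274511 23.958596279569463
26.173563688921359 14.681629604888712 26.009696139425213
26.176543053018605 13.30844038961834 28.027056232251798
26.373853683063114 5.8026701680514057 23.929714821661783
27.591147780726942 7.8270870023451344 21.798813204700384
28.573206244611232 7.8327186226866399 22.899290517188625
28.58922899705335 7.2459217857014853 23.783410954857647
28.669537465061396 7.276841490963422 25.816016446952368
26.633856297353798 7.4646353684247515 28.003524426702107
28.700641664497823 7.676901607327312 26.429310998437142
28.508646789640498 9.7945296383607872 21.69623664099592
28.581421912276099 9.7957558866507881 21.753727492283627
28.747193838221598 9.3551279392552438 27.814194351513621
28.747265817451506 9.4738715564710141 27.869288393196811
28.026675826612291 11.725836844199641 21.725281712721102
28.599795421905871 11.729539219323494 22.062361269779913
28.71783364477449 11.358601642987209 28.004749681911356
28.585293329388435 13.603568793499372 23.681046603066772
26.635500634460882 13.172227689512301 27.992326529353207
28.702037875984761 11.874188420515321 27.808088334630206
28.63306026419232 13.38622830600112 26.67584441952777
28.58411595893158 13.665066029004155 23.777089197718006
28.597256978264937 13.922159124703931 25.831207702940979
29.126645072933844 7.8310786484204389 23.732942217037959
29.139531368062912 7.740276392297698 25.772660671553425
30.055894056533965 9.8128647542739724 23.617102377878833
30.273085183004568 9.7349552323493374 25.642679639537548
28.82884679290801 9.4844304356978206 27.805331440466201
29.976582929516614 11.730933296817868 23.614714436312951
30.370845083492284 11.653208738515501 25.626801762518795
29.014484618315585 11.398436996791608 27.777440824559157
28.667033275754996 13.600750944276438 23.768361694414569
29.198231338524529 13.487922931936822 25.768622242328401
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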