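# vtk DataFile Version 3.0
tractsurf surface
ASCII
DATASET POLYDATA
POINTS 98 double
20.220657908961364 7.2352126330338233 23.533780845619184
20.887511927806354 7.3139230381129581 22.214206357777353
20.885183601643067 6.4190718869028842 23.532770314055771
20.907822542399128 6.5977471811260191 25.709702800119324
20.39858825470035 7.1715143852534915 25.70162848589603
20.919967186978838 7.1536779008330349 26.550263237657546
20.792895256828523 9.4022263283424437 21.649194228342807
20.93861854363611 9.4150602435239179 21.529244568018036
20.919777347904759 8.8449612033543215 21.609475967615946
19.416161809208081 9.2777269454457727 23.645010400828106
19.349034634657638 9.2354014582672832 25.784184226105694
20.969446664770086 9.1714021697594319 28.130017556665933
20.956047239641382 9.2013724351548642 28.131036229284415
20.970280795473059 9.2010464801279959 28.144530573736105
20.965742237494158 10.280165018145809 21.732497052067746
19.498945924563621 11.40208043087971 23.858076360089338
21.019543017473818 11.517332563380789 22.068910308006103
19.285085245151969 11.375117695122695 25.987837438018786
21.026696717642171 11.379930107598426 28.286159953973794
20.986004153680586 10.055942730149372 28.197998604759821
21.034908087494681 13.648965658039534 24.144553408982592
21.123214308630825 13.655060133517578 24.037674308954184
20.806088555519484 13.622964690641592 26.286164269676732
21.113100040685595 13.633449219797432 26.712358082972933
21.127366538010488 13.732437550605098 24.155548976236016
21.129035508263595 13.904970291812521 26.325445869439424
22.67711165277397 5.3050681272225919 23.627646576883048
22.949241965253982 5.3373261707780397 23.220418342883207
22.951526683588057 5.1909983949138914 23.647504326309164
22.941360226561098 5.2766997721810487 24.430019106858946
21.416343133567807 7.3715582420615515 21.537358695582384
22.956946213168045 7.4976910661902476 20.757447335938966
22.954339759184265 6.138122590067236 21.578773453394813
22.934265217372658 5.4544171689622347 25.843186315348422
22.899855166180192 6.9424509307162605 28.183217973942423
22.629394757700613 7.1110176411160069 28.16340365326673
22.897330156667127 7.1058642364389968 28.331063687557375
22.981641315176923 9.5792901909906334 20.611879878868958
22.883560643607865 9.1670776832989027 29.305529620949169
21.36690942486722 11.544453979908758 21.866631422361952
23.040935327387889 11.673869237602247 21.177606934102585
21.061191225246816 11.379937224160043 28.310040206427459
22.917038817510754 11.373994327445104 29.35264646902565
23.098136781089117 13.126053886163159 22.061073981208935
23.126692726302295 13.798781551424526 22.703341267284664
22.999094627738696 13.375067979513066 28.565657109237925
23.017183698299064 13.676504252957047 28.340759769172283
23.166133511961345 14.838568391524877 24.298723775163044
23.12906213816035 14.962802224992407 26.466332807080612
25.015379353873396 5.4089903629072342 23.73213329763519
25.014928522985883 5.371447051224127 23.833050635695717
25.007964187146619 5.3890418362276735 24.071500271554186
25.031548957904583 7.6019600509618481 21.027302182323897
25.031820695712963 6.4612961189285736 21.736881384818858
24.958902120581151 5.5514474596073482 26.049794954928895
24.854095593416965 6.968191766618939 28.394774594884041
24.845577607856665 7.1323676426365958 28.546437938304013
25.04139098196211 9.6970749592647358 20.779841285344794
24.782747417203133 9.1821677849717496 29.552723418552564
25.081414419822448 11.799504870220513 21.267875546321491
24.797913885324977 11.397016868364826 29.658510413987742
25.12200566326252 13.247789616214796 22.108673004538606
25.14238591101704 13.925171737330551 22.697546712888929
23.980828347125691 13.700871936211266 28.615799670990643
24.91222617084992 13.725531070793846 28.783030368879192
25.163034817054026 15.055652779866321 24.329126326057491
25.098819987148865 15.308042736134171 26.49971938070566
24.927012196623338 13.912534049663536 28.644454984889016
25.076504055752242 5.4058433754888702 23.839510227393188
26.21078766243501 7.6226370319436674 21.857857930997195
27.054341968038099 7.597957860463187 23.141044881612519
27.034236048680597 6.9423393025302857 24.054684856230239
26.935890824925508 6.9138144748710202 26.290281227050482
25.118264629108683 7.1487930377377484 28.430619747129636
26.885588356349515 7.3305179800544549 27.001005806691438
27.019025225863377 9.7529852112809916 21.984452408594198
27.082403311479464 9.7532969455475733 22.053224043702532
26.755050863399561 9.181358086149082 28.642068763677333
26.74986625062764 9.3170883186622984 28.707956890993106
26.597242566017972 11.860938198668235 22.060551971343127
27.098108723206689 11.874173494427623 22.470577749166406
26.745425139759863 11.521887937380992 28.887142091336759
27.101437786462697 14.001590834262961 24.191859407730423
25.275079282861011 13.746640424260097 28.645806532396541
26.770576901185283 12.130979146611827 28.665906048558004
26.912568988317801 13.880450791992331 27.396713339306611
27.100202513846916 14.074588555538751 24.292265657434097
27.000591425180755 14.46219655975508 26.470054828211115
27.488029743332255 7.5635622029481802 24.108473100352125
27.310557972424117 7.4021877194511063 26.338414468716429
28.237782302472851 9.7095268155506496 24.214260928998705
28.180293952058705 9.5671196388672346 26.451346493576018
26.817373906731984 9.3250550513592341 28.648835209374393
28.175178611013294 11.865463290761172 24.256292405995101
28.270073335422097 11.761277914328163 26.471454039409231
26.987434801962308 11.548778317933058 28.673815975160618
27.165226690313887 14.002295020059336 24.29038346082827
27.440832748172735 13.945583958863883 26.464754438483052
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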