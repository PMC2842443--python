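# vtk DataFile Version 3.0
tractsurf surface
ASCII
DATASET POLYDATA
POINTS 98 double
22.404136117471566 8.747751839516603 23.140635574121198
22.930541197167596 8.5948591242302896 21.895667896681058
23.003708084230372 7.8709618565811255 23.118409579258142
23.117627036661837 8.3101138008366036 24.928826488806898
22.653041328590252 8.9174996746442829 24.955279982440231
23.150982515569201 8.9557701226696231 25.575417720052993
22.737080550622203 10.559413948913773 21.188495262049123
22.863112359812646 10.540052916791188 21.063507136261954
22.881539757228637 10.005682522928854 21.200591227371248
21.579105597294937 10.826084635185232 23.154311606014637
21.587411391971468 10.998701647523799 25.024928210424576
23.123674104812476 11.036014119762672 26.728296226475734
23.108913125888982 11.064471593041143 26.729404983747134
23.122168934269766 11.064652425357691 26.738376416521923
22.847292016526129 11.379747857406997 21.143502700521886
21.446735445337495 12.829355058106531 23.084564876502846
22.798922051500742 12.567818601204721 21.295196962356279
21.298568725296054 12.999667561214636 24.99556593870761
22.96105579848739 13.036917607264275 26.70428154324814
23.071886527451291 11.848426092709444 26.722015997106304
22.600624658991904 14.729257812281254 22.910292169021893
22.682010013431373 14.714545922406707 22.807385392365934
22.417721803121065 14.905739117575328 24.81706905397424
22.713246627127212 14.917322110553968 25.155760527188921
22.675832918161234 14.795624645723207 22.903812122876822
22.6786246627046 15.132636781908259 24.793222486686403
24.569017863700605 6.5981092679264428 23.081028753395586
24.787608329592395 6.5548477429472278 22.708160909210694
24.804957064783466 6.4613999107250955 23.080689473068613
24.848191019856852 6.6540058670039954 23.727263982463665
23.35650149106495 8.5099072803637128 21.23178998388115
24.680267906066597 8.3791905912223825 20.383764611351385
24.711136717029717 7.1448862302663763 21.228544345104094
24.910114388653426 7.0236835477786101 24.87409368704423
24.976473498658468 8.8260773405694835 26.65255886957577
24.731056486155445 9.002240588916532 26.655126174351739
24.975998327744414 9.0046648865210521 26.761261774871191
24.662749031413394 10.358438036206318 20.046247204784731
24.907612687090985 11.061508221889383 27.444138019241301
23.114205138768085 12.527328213563486 21.07855296601187
24.623768486145689 12.378123903165374 20.331236037380677
22.993757414675542 13.036648076385235 26.719718715117644
24.746864855666981 13.021202878658819 27.39672962483008
24.566850151941946 13.803800032900503 20.97830224443825
24.526398899383942 14.483635399438645 21.492110852350613
24.552085045699918 14.688955011491069 26.634142832389205
24.520505680467441 14.93444562350682 26.423438515612489
24.43174191930202 15.597675515563386 22.827704749451712
24.393394998529669 15.923303131710533 24.717290122588949
26.629878564466274 6.532659869345192 22.983228120619586
26.633036327553647 6.5085469740004385 23.070704495991091
26.643257853880126 6.5599733424302791 23.267920123076536
26.530584004596392 8.3373222770051072 20.49029297444509
26.556765286542266 7.3138808626968483 21.201874449184839
26.709840801887854 7.0102311394712231 24.879365875178507
26.744089864566227 8.7752680813332589 26.669461823676226
26.741767788658489 8.9575193092909409 26.782250756425544
26.505671266376357 10.305771770486823 20.090709516464674
26.663688357522044 11.019565511812388 27.516347131237481
26.465277259924747 12.31713196493917 20.340412545621401
26.511280184824805 12.982287828678086 27.567582647459847
26.410247403206892 13.733317845227029 20.975534694980333
26.369041867908958 14.413032745636697 21.454041251070933
25.431205049884966 14.916781165004783 26.631826162998706
26.305739735227721 14.897599184342408 26.780217060204873
26.257343261078056 15.620702719555691 22.840086938636492
26.179320923164397 16.082624720510964 24.737491695281598
26.288305229802528 15.047225950765982 26.655286968835391
26.68885413677026 6.5396791981253628 23.070121396313453
27.605681235299009 8.378296646400532 21.174230344437131
28.40683583441189 8.4683539117430584 22.260911987594028
28.434785834626702 7.9593638677091825 23.076760990008978
28.474884750166247 8.2693377149540908 24.926932492764426
26.983220726186257 8.941040527760105 26.675691786944697
28.474596671370527 8.7874649211682865 25.48081089929136
28.286165740476591 10.371702237217582 21.120069844846224
28.344251289341251 10.376748945296338 21.180047306716308
28.409765574997916 10.783509534959625 26.752755021556617
28.402669681971922 10.916940851355038 26.804687325845507
27.832455706135178 12.359269682692704 21.040350347267086
28.284928203149626 12.390369811262881 21.40847601976801
28.268251641149131 12.89442061975601 26.933999369706477
28.161037776298812 14.516885232814346 22.821466218474033
26.641933885155069 14.879992387749514 26.665477871734083
28.227208502019529 13.393431955629799 26.742520984295702
28.106102336201523 14.767398932175334 25.632188104294439
28.154104146516435 14.594138470002733 22.907652788233811
28.074654224002664 15.183428986279973 24.814325091986515
28.830434194373805 8.5422627354232503 23.079319745343767
28.803918782685699 8.7270807666054715 24.938942872778881
29.448126645545813 10.548981326300845 23.055748671084796
29.526766251751059 10.730648849809166 24.953427743249335
28.459625345591412 10.911590815729829 26.756767392673815
29.297239905348231 12.537727898467768 22.995933200206803
29.493378920482503 12.713232735101084 24.920003890459327
28.476185277492014 12.877343806106131 26.760012291549682
28.220679270127558 14.524895432675978 22.911105981340793
28.544172861967088 14.69592403813485 24.84102446520626
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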