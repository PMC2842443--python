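# vtk DataFile Version 3.0
tractsurf surface
ASCII
DATASET POLYDATA
POINTS 98 double
21.799948626338026 8.184995626646467 23.916332704585386
22.466309466055336 8.1418253592265035 22.614299151072498
22.407037028583087 7.3088400627935934 23.970232862704577
22.433749857861926 7.5156855649977174 26.079980054206672
21.960953123392308 8.1234976741018414 26.049309659349046
22.48578611626975 8.0542905374665317 26.86539654132083
22.489303593239267 10.144946278243028 21.864934893471556
22.63245168195742 10.135124013661557 21.747944792357643
22.584755987074235 9.59533809859321 21.885352958028346
21.110311534810908 10.235909957872771 23.828095763321318
21.019537517143768 10.186153862687691 25.974368181973357
22.684100911839515 9.9258100422098199 28.282916632693762
22.672307878770745 9.9543056843978857 28.282543144644464
22.687106043498726 9.9525612325985904 28.295236775028972
22.71524954496514 10.955454231348575 21.859899221870709
21.322232207023173 12.17767695060286 23.808663726286749
22.840159645307246 12.105584113242321 22.049623518493238
21.092219757317626 12.128663911850659 25.967891407382197
22.917518676525258 11.881179232678981 28.28458694951069
22.777555795302749 10.718589573811828 28.296394232443667
23.023572894169998 13.991379813454278 23.867427760349091
23.109982892864096 13.99024935001728 23.76080233535988
22.830378011957734 13.912956020083939 26.042114270964351
23.154601491670782 13.869400758593898 26.477892413393782
23.12079522280013 14.054300075575393 23.869701114432871
23.17860029476558 14.119132169531943 26.050376732702553
24.080695064993979 6.0196253478860626 24.075181353709358
24.344414020982683 6.0098292812534684 23.671778104634246
24.336840353552265 5.8801800713512877 24.087571879527502
24.34724982534437 5.9919523036071718 24.839464403398203
22.979247563876452 8.1043227779366678 21.942869395993721
24.468494331932231 8.0163490316720818 21.160243930778869
24.38542730329544 6.7258171102874273 22.041190434248676
24.365532093391575 6.2046521861097368 26.180232299041467
24.491233255396601 7.688861424235478 28.345077553410814
24.22999899446534 7.8704215324942224 28.335505331314284
24.505689502056324 7.8457634202141122 28.479287261886203
24.616686775050862 10.024828376153472 20.849192606194386
24.701083641395666 9.7483702927364924 29.331685194678535
23.181813198670081 12.088120139059948 21.854646616710742
24.798021700109551 12.019924179927115 21.182536632522218
22.954089028206393 11.87713346374848 28.307599228742973
24.923708453296705 11.671140744471254 29.272924045576204
24.952286181017797 13.353682037499681 21.881659275249945
25.035695341789623 13.945760662813877 22.436352114019019
25.123908048486822 13.376193548184032 28.352659740667956
25.152682481176896 13.636104895491933 28.100735027813109
25.185662648892947 14.803893039401407 23.899928712104348
25.253698045518728 14.803074122931642 26.072535802760115
26.361650302045462 5.9096571496564989 24.075343325146797
26.359958581111741 5.8764246122971375 24.172408614728539
26.363354530943937 5.9021975739483148 24.400242115696717
26.469744302930344 7.9423486395368883 21.379042492369571
26.407876623177895 6.8614190230262189 22.121614007049445
26.388040226089309 6.1259709111321987 26.270816505300555
26.508026130524794 7.5511406765842715 28.439932200841991
26.522226486866899 7.708950933732841 28.578451001871993
26.600780550939959 9.9524000139484947 20.9908076317435
26.709705875593979 9.5898460201761537 29.477439661758112
26.759041444667218 11.94575652045055 21.262105584574474
26.919841774724489 11.494491403222129 29.506001109839215
26.896062434449473 13.270220793594325 21.924550150321593
26.971445674781208 13.865125350466011 22.426081464288607
26.16120243498677 13.538871245117885 28.360080051915698
27.12950364783142 13.449340923469556 28.515265935262097
27.127052944921346 14.79085776360256 23.915713361820742
27.222399420836698 14.882157301734839 26.073764040949477
27.144781420969476 13.60892737313597 28.363159235777811
26.42331257185818 5.9049910356821407 24.174918083251075
27.626942150242819 7.8945504289823294 22.146849944677584
28.499063386514791 7.8275231824752449 23.350095410610574
28.471886328557002 7.2242295207787599 24.245893538404097
28.501331464330921 7.2543799946719831 26.369773968078292
26.801794646718459 7.6964484451819972 28.456562176505216
28.541822129469292 7.6619887974244136 27.033071112182999
28.544098468259197 9.8574868682687917 22.118859481187577
28.608894960200605 9.8524977072336988 22.183902116955974
28.710269583356784 9.3725017688677834 28.550950999519394
28.722394040480978 9.4929464688954965 28.61098909873623
28.250331194462156 11.859175884497692 22.022476373981988
28.757628465496193 11.817440646308642 22.41651686321827
28.917854131268733 11.379456648683059 28.722852689982069
28.973183228168004 13.663777676097263 23.903978219860136
27.500234379940192 13.425833268458687 28.376042417330304
28.969216104879287 11.88856405960156 28.482969989447351
29.088166974472326 13.386872764550757 27.123482494034477
28.982624873800859 13.722866829509806 23.996459745555043
29.100872954528555 13.931528292394962 26.144120914377506
28.97004786858361 7.7732512939701541 24.257547583068121
28.927175271220566 7.6747388037022732 26.388442747346865
29.880429348037172 9.6920950126362904 24.242894126382783
30.011281163304126 9.5478335799781497 26.408052986377946
28.788537414581054 9.4917960039809337 28.552899942051049
29.953360952070057 11.643593391241113 24.15206651901666
30.265477242276731 11.456324201795274 26.3353251153112
29.153557725155743 11.375028402387768 28.512476193185048
29.044216411539139 13.651868970500121 24.00215959661837
29.529183489405668 13.434104117794824 26.186047355156688
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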