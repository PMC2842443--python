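# vtk DataFile Version 3.0
tractsurf surface
ASCII
DATASET POLYDATA
POINTS 98 double
21.158328970688913 7.8138133616671741 23.961257865010001
21.836706996090985 7.8158255240163719 22.769699422018746
21.812274995276645 6.9473816116812142 24.00898012721915
21.742273016809023 7.15250734806901 25.906417706772604
21.238229695458859 7.7548043695207678 25.868252401369759
21.703129287405464 7.708447213081036 26.587730514090453
21.696574707499881 9.8830589751310445 22.103251714102317
21.841185593839754 9.8791916432042886 21.996745961029827
21.840441766568148 9.3193500093023776 22.115914814057536
20.299394690316838 9.905960253259007 23.878368096000788
20.142369684828509 9.8618066057625189 25.765289146726424
21.628713468634942 9.6773596748556958 27.754594854180375
21.614539111075413 9.7069671031393643 27.753185747378943
21.628230769690028 9.7058477875069613 27.764163374251805
21.832704601756248 10.723154489982448 22.109714665232591
20.273058332995788 11.973933111445305 23.836976072332522
21.829839593374952 11.92270206053681 22.28976572426458
19.978400867051487 11.941139153395698 25.709678802615148
21.639389324211407 11.761134716929734 27.686166735130257
21.624575957380632 10.514134827301 27.735208821296116
21.71536015994451 13.941725159333776 23.8812853274936
21.806752918738056 13.937597647547287 23.791590547828712
21.43248426680638 13.908184664416098 25.737071008824916
21.736510366900223 13.873464870695107 26.1128561315005
21.805843642262037 14.008974619634778 23.885125072377139
21.756181372319208 14.134853928403784 25.747550261517244
23.52674396387572 5.7019871836933067 24.110439827571284
23.79703195919571 5.7028359248166272 23.739395591616514
23.787591688607549 5.5695966198942033 24.123455158509799
23.76020667425113 5.6736408173931565 24.815097181091293
22.357359585221179 7.8142540308231734 22.146846056460802
23.848648454091251 7.7783174774794173 21.425101596181175
23.835632491501588 6.4563092739260899 22.223465604429311
23.712408490222685 5.890841802520141 26.028287802394438
23.604643580596328 7.4251704068668243 27.903995923674909
23.330588737890611 7.6009729444728622 27.88673061360404
23.597247848386239 7.5886644823841474 28.015217890889954
23.849679373524449 9.8084420851026124 21.198957038408899
23.553975695529346 9.5817212053003828 28.67719002492781
22.178624082870169 11.906591549472031 22.122040854151539
23.84974416542217 11.828613591938703 21.567455097200124
21.673952149228846 11.758143670340978 27.706072701879588
23.592656743749128 11.62242660898853 28.564229256642093
23.850227223413718 13.202486216071087 22.224393305657017
23.849513661869761 13.828490233050243 22.721266266161049
23.690767769046655 13.433234278972305 27.755203997039395
23.709906931374064 13.705638472345688 27.540535815789493
23.846930863555752 14.782355573210552 23.990320800991885
23.80980191646044 14.881089641956674 25.829950493470506
25.782750943044299 5.6388127940464141 24.135513817960678
25.780664048662537 5.6058640335514349 24.224594102348043
25.773012714964583 5.6308386490876732 24.434643633454527
25.843166606383534 7.6988550100453752 21.670339986764994
25.828099349643139 6.6064347512525536 22.333772554941351
25.712781680077075 5.8709799522963388 26.129609335398285
25.621556880424837 7.3635334833172159 28.010456491515711
25.615551931159771 7.5292826608224779 28.125937173464944
25.855930916656053 9.71368208239155 21.391245374522597
25.589434416130501 9.5120722919996616 28.841502434423223
25.870758706274405 11.717887291501711 21.725956067884212
25.643805650122562 11.539863284591695 28.821498634267709
25.883396073124132 13.07742197710132 22.363758586869711
25.891146084195881 13.706962434751787 22.817806068231835
24.749334479830054 13.645646493099472 27.797379547619009
25.772527726203599 13.604961225503709 27.965880946958958
25.906135889052923 14.751129859372323 24.107370151651981
25.89159610775269 14.995259951597928 25.920131065222954
25.785190727019103 13.769464268926859 27.837477049059476
25.841483255464897 5.6354831713918658 24.227936768374967
26.988964505766141 7.6474398850740215 22.41102253211421
27.838569753510587 7.6075035091930046 23.528198902154354
27.819924755075334 7.0151979666879765 24.328221682647587
27.772137517879997 7.0991740674037818 26.221329170375203
25.904174344537484 7.5253904782085179 28.023182166170987
27.755499009243096 7.5373317849527917 26.799048735706947
27.81366799924082 9.633364747266457 22.474814595242471
27.878391305569359 9.6312747682910871 22.53475871154745
27.737349841885539 9.3779595264017601 28.082393524401201
27.738667123513995 9.5078013340560901 28.131763991311484
27.393030570539462 11.646065063304855 22.46201651560056
27.91060720999528 11.631137695622987 22.822506623065852
27.798727249337631 11.525810497381011 28.206960942022956
27.957282283851971 13.623720209244164 24.159792022358165
26.168182084531328 13.592972467273791 27.862745406695772
27.825579629601567 12.060362326687592 28.002227905258728
27.921263858047261 13.58223804166572 26.860981348946407
27.959448423660103 13.692405824373566 24.239125114607404
27.959756035009875 14.087145418314416 26.044039669910251
28.298367417748565 7.5918752084353871 24.349254940935008
28.183345753675525 7.5528050602202095 26.236091046392726
29.133438102544584 9.6011361988832871 24.373712883737969
29.195863424115693 9.5677100143333664 26.249308010669267
27.811225511140009 9.5091439723952611 28.082709566081512
29.104193485509949 11.613009023003665 24.340992793771896
29.350316121269756 11.590110138918577 26.198006182079624
28.060518372290399 11.530473953485398 28.032531116348871
28.029183479953247 13.622362187553554 24.244313723626437
28.446524980314532 13.598680895387645 26.084528045538015
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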