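# vtk DataFile Version 3.0
tractsurf surface
ASCII
DATASET POLYDATA
POINTS 98 double
22.034127889444282 7.2948236249377167 25.657653944678096
22.65805086373215 7.4223039286256665 24.155546433357905
22.663194432425438 6.4947066709376102 25.5363379262037
22.722634185509321 6.603519930026021 27.774654998454288
22.233357398020232 7.1457484989419839 27.862059622691024
22.752428486298573 7.1268196143459619 28.623775677998744
22.567731255665088 9.526809817505363 23.510121602613768
22.710007023075711 9.5389426554837211 23.359952289761406
22.69425659714765 8.9666624886274633 23.475242632511883
21.21534548439644 9.3003132813527287 25.808011329701923
21.14547820088513 9.1160119479519306 28.010294895182117
22.780390808441457 9.0663983030628152 30.103442679500379
22.765963608868852 9.0945553913911485 30.104793009755625
22.78022437381043 9.0950344932922871 30.115400639218748
22.74480279648678 10.395060996858671 23.527706586145928
21.228507833143787 11.407262529877562 25.807291377625745
22.785868793606376 11.616908271784833 23.778643488943423
20.979999482822002 11.21271044549683 27.981431531818252
22.760126761062295 11.209009708018614 30.043558247426418
22.777206216452846 9.9253370178641678 30.103413930243541
22.746471595484177 13.639143453440694 25.683898559208473
22.839274719705411 13.649008638475959 25.569184688617501
22.468990900373427 13.482507983242394 27.822002022489723
22.779835784640301 13.471909216397178 28.210804001686448
22.838785402208178 13.71976249767531 25.676699659710177
22.790501533967706 13.762959098753058 27.790962692829634
24.318942756987887 5.3835040236440221 25.247821995346296
24.567868870183968 5.4088523160550217 24.775469142199238
24.56887051272912 5.2653619083012551 25.205872946799733
24.588632640806388 5.3499329359406929 26.01389000067342
23.14785591102531 7.4832863648211116 23.340001326313875
24.614127908791215 7.5297356094920751 22.243675584371971
24.56945475665632 6.1937667393887494 23.090573700514
24.617849128120579 5.5277945725238027 27.445037015353975
24.681745931894145 7.0099609923044177 29.795077415845959
24.424917479805593 7.162006346263361 29.842553322202967
24.684907561631995 7.1720945865228387 29.939858541398845
24.705907008936517 9.5785307497400165 22.062675505638804
24.695222416333969 9.1839636752656304 30.840713283087062
23.137507962590956 11.634241278195924 23.523019753763357
24.803395008912201 11.632276886994983 22.571123241129065
22.795517281263443 11.210417949485166 30.061759106990259
24.678621361837152 11.276127476676139 30.746382049262447
24.861240062511495 13.042929586842805 23.404193332681064
24.877764727152876 13.689853750066831 24.015815240685647
24.683684052755229 13.155366215790977 29.804319804417155
24.690522849250453 13.442404959146975 29.55659460215837
24.864292858251346 14.672837009723043 25.522810059149055
24.774725489440392 14.722464424076861 27.612532545691817
26.527058614512196 5.381208013508985 24.87601035158271
26.525550045288732 5.3478638531747649 24.975084167057474
26.527275903481691 5.3711654737177064 25.215109809780177
26.619688847085062 7.4260270287483934 22.185545411459238
26.568862344573542 6.3454391599878264 22.892477100835617
26.536052454812602 5.5934544615602029 27.178555587767491
26.566490360961282 7.0699209604382283 29.498527160636591
26.568080043452376 7.2359705837573891 29.64716349245959
26.715992015347098 9.4288488349001476 21.930584962429414
26.571011156215828 9.2355332288914518 30.61201173983924
26.804675429932459 11.444406693142522 22.392559075335232
26.558862602806641 11.28368839095827 30.656458550026137
26.84710253475173 12.830158398141764 23.209094829727725
26.853428349422305 13.47845685270809 23.78010866631476
25.655391576078358 13.417342366135783 29.688086073785961
26.576528542915629 13.368659175799278 29.712689607317287
26.813802513886451 14.562741296518846 25.347613484833516
26.697773923252541 14.805549516425112 27.429993671624398
26.582133998656346 13.535829960357027 29.569633963424096
26.586328876435346 5.3767080332443555 24.970216883343031
27.762234500260274 7.3030204658504019 22.837108939680959
28.580748002958106 7.1907490003313619 23.955692392316621
28.535762102540012 6.6299986439418674 24.828163518099839
28.484691504027346 6.7444960967899945 26.978833835396834
26.828546197406482 7.2384502929899597 29.465171158483262
28.478553218829155 7.1845592051853444 27.668381920464945
28.625330704004085 9.1496890419667878 22.858240935545915
28.686216321434124 9.1388124421929327 22.916668218426821
28.45869833371243 9.0284071609698238 29.267568380645773
28.457324604621 9.1580613092476337 29.33240247879727
28.265377314591035 11.197291478558645 22.996348908172195
28.741736901020531 11.101605002465133 23.334833762404664
28.452886276883739 11.149816095278858 29.530114103586648
28.713023599231825 13.105643857754929 25.017333080483837
26.936511413540693 13.340539078619198 29.53154249436038
28.461467343731876 11.66847015761998 29.324163869095841
28.526616808092246 13.133156622543773 28.113607379593514
28.708659760189772 13.176274979239579 25.114634075780106
28.583271285480084 13.614939692697471 27.218800544155499
28.999371395356778 7.1360044113105765 24.805704128029792
28.864509337520595 7.1514387031489015 26.949157761006305
29.794629757958035 8.9355578716071804 24.812453978130055
29.766876773907327 8.9637804836264294 26.914998776570123
28.520556605774495 9.1519506465952283 29.261151880185786
29.761156116660821 10.878817506714897 24.90589433038129
29.866175302537766 10.882440911974072 26.978965409044982
28.682293544421718 11.118663423110934 29.28191023423971
28.772578355335117 13.09196784112355 25.104739385768653
29.026614350964309 13.035220751114311 27.1536139111785
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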