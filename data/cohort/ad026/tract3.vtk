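# vtk DataFile Version 3.0
tractsurf surface
ASCII
DATASET POLYDATA
POINTS 98 double
21.425921455947002 7.927450992059093 23.617980173737401
22.074581056455109 7.9065980563141167 22.357950130560347
22.104322509530341 7.1080699428051446 23.608752736503579
22.143795352190921 7.3672733867629177 25.471038222014599
21.619517565190971 7.936864591187593 25.478943867746001
22.160318543338896 7.9188459682880712 26.136500354503376
21.908068828238918 9.8606060593726035 21.655272377651244
22.05196154973715 9.8595182484893922 21.527439187943653
22.055266599778967 9.3291079067929097 21.661512745111445
20.541295870835363 9.8809256671299757 23.662386428459168
20.47945114435916 9.8905701521999276 25.548087559311963
22.20389740203866 9.7797846227819125 27.306925554643293
22.189213003888078 9.8069527202184634 27.307443970766368
22.204534728155618 9.8059403366774109 27.317041035259486
22.062186210788571 10.659591242645448 21.633029780835916
20.552685403887516 11.789090863332602 23.669522385753115
22.08651875257841 11.78712987154236 21.820495698228839
20.349644489569592 11.780076900196944 25.588226062667179
22.260726643106693 11.653374654063144 27.315812801411592
22.223804551262003 10.540041013031503 27.314005491247404
22.148813470574559 13.631672607311497 23.579912906259988
22.238230576422616 13.632783034631098 23.474337709100176
21.982467435315836 13.56586199696444 25.516672420023703
22.332179757221869 13.533270198215748 25.863309037862962
22.247003766683527 13.696262169646712 23.576745848258607
22.336324653853808 13.773024354716119 25.509631390826755
23.8683758606733 5.9154802132610271 23.636342207058966
24.125782292738833 5.9075071899013984 23.261182581973284
24.132988027803329 5.7863036303129505 23.645269711531139
24.14989298410233 5.9070563022246922 24.322444994436541
22.579025179785475 7.8986669268730125 21.683161573537426
24.069517734211036 7.8770704013372495 20.853459066935628
24.090182338294881 6.6057532859582402 21.724360378631271
24.174945097079014 6.1465001210884793 25.509654736155927
24.227879964408046 7.6467174493203593 27.335612807842303
23.949881997162844 7.8205765963638889 27.32406294865017
24.232487760160936 7.8014937593739724 27.445231033605097
24.070458980887775 9.8391617256690918 20.515611746423033
24.293732068138382 9.6388465917948078 28.127144302981979
22.438227424918317 11.785181410783894 21.597151224850087
24.119603974054691 11.773861684448823 20.839090395945583
22.299105353973541 11.650261061160329 27.332529887701838
24.380241430498167 11.453845796519525 28.095347404101798
24.207533928230902 13.061051870046642 21.557732807817469
24.273722377563001 13.631919875026222 22.12498947461631
24.481918839875718 13.0614429249097 27.396044692253785
24.497886998143994 13.309309509445249 27.199026678066954
24.425666372630591 14.462715219892036 23.57268122273527
24.537542827873157 14.447168386303593 25.536984658829269
26.158810152486733 5.8451588310234079 23.632048312692142
26.160451115913936 5.8138547831741469 23.721786577554422
26.166730575395473 5.8413347957293134 23.9286706208994
26.105728742280483 7.8276496525071479 21.060961238804992
26.117304670055059 6.768444972654919 21.791585747886863
26.209462087781979 6.0900474085177976 25.599898035011936
26.279881414664342 7.5079003684923507 27.444680564092632
26.2866870777682 7.6613024800055456 27.55939932077596
26.124163594410096 9.7823169829375161 20.658075083215422
26.376314946676285 9.4559912232614725 28.302154445132157
26.198124171811362 11.704285188815021 20.9359197357991
26.496353568776726 11.238666065409669 28.372046514495207
26.306073640708078 12.973288393439843 21.633194962033024
26.379743564179453 13.542930683181474 22.157947930871515
25.593908767924706 13.190772049922744 27.460332632646992
26.648031132864606 13.078011139684284 27.656362075426141
26.560306079560725 14.427981083971099 23.661184402768832
26.701878440451051 14.488003199784842 25.65386580751121
26.660066681792877 13.230849696772987 27.539474576460215
26.222519455501413 5.8422373862828998 23.724317239275152
27.296885633244802 7.7782387442100536 21.832842345397047
28.204135964945202 7.7172089346468837 22.9967980418119
28.216344197388345 7.138851908623348 23.822505431505306
28.277337057373526 7.189986875204653 25.71824643842832
26.568902956055211 7.6451579212372387 27.462402641903171
28.309717393969944 7.5895444026043641 26.292047453481029
28.156190327274622 9.6755630283950751 21.842360477368903
28.22423958006879 9.6705577584069093 21.908093523435682
28.431036745701284 9.2266790968311945 27.602348499519945
28.439885800530785 9.3402166609114747 27.655937058412199
27.796567876273926 11.598395797685104 21.762081965060837
28.340479261037189 11.553581815182152 22.175003691347339
28.591844812159334 11.108831568761907 27.827444902664435
28.587845866646166 13.312253823218272 23.696095887506598
27.047816198375308 13.048849253225013 27.564332770890882
28.635727106373068 11.587662053755558 27.655338114003133
28.748487675960774 13.014537576820537 26.600358101299392
28.599921181763374 13.368270586703327 23.78789342380551
28.759097836875736 13.545879869930081 25.781911160406445
28.695920210756448 7.6739839832432573 23.848849021115708
28.688499428419455 7.5972535806711647 25.74470801529074
29.564504121064651 9.5287791690512602 23.890179073840329
29.728297540607834 9.4009334217294889 25.816531943153244
28.506951174982611 9.3390954509803947 27.609363348039864
29.623394016285882 11.390726572997989 23.87353371852133
29.972162185088944 11.215158614018696 25.840750724412697
28.83607002742232 11.107200643248857 27.661510996100965
28.666196044310091 13.299980938847082 23.792574979149911
29.213882912998979 13.074369306094862 25.806783811923104
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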