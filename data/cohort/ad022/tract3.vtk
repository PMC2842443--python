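# vtk DataFile Version 3.0
tractsurf surface
ASCII
DATASET POLYDATA
POINTS 98 double
21.655645208750791 8.0242435120288178 24.560480228940346
22.274261514408611 7.9960502385458057 23.204851093996439
22.292258154311003 7.1914094718797337 24.41348461056662
22.349627857424231 7.4614266409406902 26.414697689721855
21.866953850170926 8.031630397671325 26.516144585827863
22.384294018370902 8.0300861128570737 27.184793950048153
22.131601452998058 9.9781475815485923 22.793356981444628
22.271168196794125 9.9719926058062267 22.650933066534002
22.271976635969498 9.4353562947903153 22.699025793687927
20.854211331646312 10.017793865377818 24.91973920590998
20.85229644710288 10.005139840174456 26.869857855959232
22.46324920587481 9.9572835593603397 28.632540761634086
22.450123404927243 9.984524166114733 28.637099987231053
22.464024038398627 9.9844460036466369 28.646022431909557
22.277697261136154 10.79500795265643 22.902409603129641
20.872340536252551 11.979895162200078 25.24296042599962
22.28164607306644 11.954156499146315 23.299542470917675
20.75292540006577 11.949350545781988 27.175854108730245
22.488480672826689 11.915908888411886 28.845979890074144
22.478348537524141 10.753294655021923 28.725070183170814
22.251884562518093 13.923253464318039 25.363552895406166
22.332151240894405 13.923748326925905 25.251525812241876
22.125451105265697 13.886075702947821 27.27482945883084
22.432973070139589 13.87869521739097 27.58376288410685
22.335688909990459 13.992901831882689 25.360554576230896
22.415923432421941 14.122348348564728 27.260765580446606
23.994679258697293 5.9856509970080793 24.187440921576123
24.253150372886957 5.9704267743288391 23.766826028810257
24.253618433359502 5.8549649330412237 24.162113524539361
24.262915441124854 5.9960482787992149 24.88993390865166
22.769996351023241 7.969371904288316 22.463281171080634
24.261962060782622 7.8939303365871254 21.452494419458464
24.251749157031604 6.6355425331176292 22.217221089458093
24.277163546591847 6.2656334558435063 26.172745993808483
24.315899599488478 7.8615141513590459 28.253430290198086
24.056803365383626 8.0265348265262517 28.287957434044532
24.318455721878973 8.0259527083582256 28.38412129490483
24.270394259158468 9.8717977090519256 21.384709143090458
24.332928906246593 9.9822719059001592 29.271301950121277
22.617731937257439 11.942079806189609 23.039777476677497
24.25906789504333 11.867104813369036 22.044580078913036
22.522056082672968 11.91577581540108 28.859793224013163
24.317879402840326 11.913822007945953 29.388303437857363
24.240109939027445 13.247532999030334 22.986903132328926
24.230068060335778 13.88639453798776 23.637506082975648
24.282621571590337 13.603284993923202 28.793435243944508
24.275484898849236 13.85916261019845 28.612806556156496
24.217831702778408 14.867211018284937 25.156316189282062
24.233683384474396 14.981472688965288 27.056407523398939
26.260406637129194 5.926466984530677 23.941630814019188
26.259227317777263 5.8982600128885885 24.034533528765991
26.258732803237287 5.9369849565428936 24.254573727951701
26.304938966128752 7.8096531624917098 21.398158369121003
26.285965303409974 6.7749435271729475 22.070430228689318
26.249386933428767 6.2699803049883407 26.041758990340359
26.233223710554419 7.8461880868637017 28.097080773472975
26.230729950038981 8.0148658419130214 28.229257115860211
26.318601815957273 9.7767129445472296 21.199666221303136
26.191255897229823 9.981274233124001 29.13332803732564
26.294595162230593 11.777777104814692 21.753869908379095
26.134456862570094 11.918632432150124 29.31085312972213
26.247606167187378 13.169338313623097 22.642416270409417
26.214849439737133 13.824381756436264 23.2425385934704
25.193100675381814 13.861900616791502 28.678052594506244
26.078925958417308 13.863305544828368 28.67001081660317
26.136436951203805 14.928671899749576 24.819144536041076
26.075096200088826 15.203775530153695 26.761126100062469
26.075661407614959 14.01957598202533 28.559312408114977
26.3208256477254 5.9279334700576278 24.031743923503015
27.469867125675702 7.7887032385816859 22.023298118964767
28.309259841904669 7.8088484644189577 23.105205118165131
28.283636626546468 7.2767386125958353 23.946303004232757
28.227911774018089 7.4827588408427737 25.954513683676442
26.498165694343434 8.0109920019109389 28.084615279842435
28.205541539255762 7.9542103615098085 26.579861129095278
28.277498058231586 9.7334267377953747 22.051042182981821
28.340193296716528 9.7338141750918457 22.106827602402014
28.110522649460833 9.8303860118178825 28.039456536935404
28.103619491860243 9.9587004800689929 28.100902930662503
27.802736571860695 11.742329647418936 22.25962916486138
28.297786211421286 11.739702674770147 22.568528771451142
28.012694701829528 11.912822097921666 28.353812606388512
28.149482663810073 13.809453038679807 24.29115068962755
26.424140327592603 13.866775602270346 28.496936270571759
27.997352551570419 12.422558261852004 28.194053737281006
27.983995982601343 13.866619971962862 27.180381159637651
28.141211331587346 13.881881399590888 24.388255270002968
28.006593653739376 14.340039348151727 26.390303441569657
28.741754159755693 7.8346757071714137 23.930989552112159
28.605694931224573 7.9243613102037394 25.94263281245118
29.488222805812342 9.7893549524820482 23.943704797568188
29.461678095603322 9.8793436358053093 25.947571923554104
28.168655940288627 9.9570014495280326 28.040467769186275
29.360971093436486 11.778931542646419 24.064164838206654
29.46796883069899 11.85248313397018 26.041957743517131
28.245197345966329 11.909456017323167 28.136521192107587
28.212133492168697 13.810651526936354 24.371398528559741
28.488359754519188 13.851562388633514 26.287479513946025
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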