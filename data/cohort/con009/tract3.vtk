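# vtk DataFile Version 3.0
tractsurf surface
ASCII
DATASET POLYDATA
POINTS 98 double
21.558814814589567 7.725167478658344 24.515278475148563
22.167154179142013 7.7858950390152728 23.0989748968071
22.186893365795441 6.936959024096927 24.422470662861045
22.260940376068064 7.0814748468862776 26.505351274337873
21.78058366864396 7.616614469444885 26.579829528922563
22.30732658208726 7.5814990999132723 27.28664374308693
22.047642928641174 9.7492667007477483 22.47033144198539
22.184545924425095 9.7542926282131628 22.325739912300964
22.177382875612174 9.2238246877044805 22.434837650514613
20.775854534375643 9.6427722855103681 24.707133332648905
20.77110380624821 9.5051235088155579 26.81060207079647
22.426983239139009 9.358387392505696 28.720680414854268
22.413984366627535 9.3845477837838676 28.723885088810984
22.428346507836995 9.3841583716042738 28.733683005829285
22.206978786270103 10.552766319485926 22.49931710949264
20.823505509560139 11.572326603749882 24.83063501020543
22.239956943364419 11.675806662188437 22.78191968036538
20.689352431999012 11.423139019988636 26.964849467501278
22.487777349735584 11.297335503072329 28.864115155453636
22.455161699160556 10.140249322772691 28.787427722306024
22.274022169584914 13.510160940762637 24.824478907393733
22.355484665035291 13.516529161740833 24.705470527204032
22.145325201239185 13.378648582403756 26.982413331232998
22.465436484268874 13.357303066193856 27.360201096618756
22.361479646481015 13.579216236115169 24.821384406977323
22.453016798433985 13.617059507325898 26.975150197634797
23.868570749204213 5.8209921434352658 24.263105013747602
24.118811744214149 5.835041558868979 23.832031983815355
24.124411952535461 5.7024531693728813 24.244047538621075
24.142595257035598 5.8022519584595376 24.995312763838328
22.651782621632165 7.8108686126517926 22.334770852451356
24.10135861416525 7.8339038343954384 21.335353340643369
24.09952405675573 6.561381697015551 22.199628201388155
24.177318791442254 5.9929389434477018 26.315611253025104
24.272945143579435 7.4064212613115403 28.437979435033874
24.014070953291366 7.5535629246644937 28.464514631048878
24.281057202371162 7.5568695055290256 28.570607704165894
24.123061136785672 9.781593739838252 21.106735886088131
24.356594898454759 9.4053004692411548 29.469599469257478
22.570654212251668 11.684867186582391 22.526475978269811
24.162548482770134 11.704914164083748 21.599747539592027
22.52274714014802 11.296975565266882 28.881035753142132
24.394777511641177 11.320754494278654 29.57893312210809
24.207262013541534 12.999714990149787 22.462757904721865
24.236584506858126 13.582707716104727 23.109042218349391
24.3962739279342 13.055435541844433 28.914320183291572
24.393693755524382 13.320671436329262 28.709423377514216
24.300169731412321 14.449256643940851 24.725520024538461
24.361331799562809 14.488234003448971 26.905380164287756
26.101504165833376 5.8488965765476895 24.048330390996515
26.102354406047127 5.8164240795906563 24.144586663746491
26.106192505254441 5.8430569308305635 24.371886740449554
26.087928196934996 7.8298655096977061 21.354914431126652
26.086576183598524 6.7778447433734579 22.092160016233123
26.139291652494599 6.0724370844659648 26.215573409278722
26.205632181809801 7.4878948651750195 28.339486074754806
26.211249894411452 7.6443131400998565 28.477120491915578
26.101837928798819 9.7713377902524829 21.035129124247987
26.259265378519149 9.517512702627533 29.438040561523867
26.126825012507869 11.695168546459813 21.467410454070173
26.275715845233258 11.433794877552938 29.658244094255853
26.156342606604053 12.993727333227692 22.305441965014797
26.17520962435303 13.589966242509924 22.907146089906831
25.349416276633047 13.356098106435061 28.891067643461991
26.267553630660661 13.403195658454822 28.985474709068715
26.218913292750862 14.563276124345396 24.590164220363292
26.251878320393651 14.761575215948149 26.806057831905587
26.266417651047096 13.561752876395992 28.863248473561054
26.163022132837252 5.8478227938916678 24.142359701007692
27.240088916465702 7.8235306370873721 22.036570994590519
28.099726050565874 7.8201289282803428 23.180599414049357
28.102600886428519 7.2512322695754863 24.06738419167111
28.125497099624496 7.3450635364435675 26.164455878539837
26.4767238018622 7.6625792381078996 28.337810075716945
28.13796851645451 7.7745309799446947 26.822529746586625
28.038662900545205 9.7599217421053339 22.01108005802412
28.102476822431086 9.7598869705425351 22.071661126683047
28.168567372536 9.5472861484500964 28.389149024575726
28.169572746985324 9.6712472273633789 28.457181396478983
27.614904913643304 11.687299688990898 22.112694043376617
28.11528244545541 11.687929395024105 22.470900803944833
28.169866577404825 11.59950437776773 28.778438022429185
28.139117214892298 13.602275675145865 24.25972790941465
26.619119423604847 13.432420132797485 28.833100997136558
28.16689456272421 12.111919201787215 28.617871360207406
28.156535658395029 13.564951163614984 27.510585776611645
28.140101347062132 13.667637587267357 24.365093272594407
28.152464328836242 14.042674724831951 26.612141669651244
28.559713805802858 7.8190505482805728 24.050268441817831
28.511238803552398 7.7968180474856821 26.161203506589754
29.328367484302358 9.7691741918155213 24.045403744208215
29.421355463540053 9.7656441974778296 26.196715751481189
28.232721676242477 9.6764551639746816 28.395958488875895
29.256602038098169 11.703706292840907 24.135449767814194
29.502008335470823 11.709797318312608 26.313915689229106
28.396224292157132 11.620124422651939 28.557157012116122
28.206402260840342 13.603400443331182 24.354464749213079
28.610701245585211 13.601839284545688 26.538172638346396
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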