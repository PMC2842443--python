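# vtk DataFile Version 3.0
tractsurf surface
ASCII
DATASET POLYDATA
POINTS 98 double
21.675179590215699 8.3496286150127137 24.417127160901732
22.140698245591988 8.3421795118379638 23.211525535596252
22.288666950822012 7.5085449593915907 24.386486044134543
22.50048161503215 7.710206513086221 26.246175648439461
22.02685232228961 8.2893549583424093 26.259343012079295
22.574785085259673 8.2484646981049856 26.934676163869305
21.943448427816715 10.318164846841778 22.610062878842967
22.061425234002339 10.312915231436905 22.492086095692621
22.068243885535328 9.7817187971564223 22.604282056698814
20.908861447582314 10.33973175039938 24.450767132817305
21.018525955725135 10.272861436315138 26.27879428481188
22.692220477890967 10.116086878986287 28.142450159220601
22.678634359880697 10.143545899320902 28.142306268345955
22.693075564904984 10.142739558198107 28.152524193615694
22.096741222386026 11.123565470389526 22.598567720503482
20.95267375522786 12.273916331081749 24.423849412189277
22.159828992030423 12.258582385194702 22.761619117544633
20.909889496790996 12.201476009267475 26.254258752147901
22.697487324353027 12.073410447086792 28.090079450288556
22.695196889647889 10.91210389609869 28.133689078730718
22.345713757186903 14.156426496369122 24.297087624327183
22.417402624869101 14.157391579489641 24.199439656934313
22.298745912209746 14.086013605179385 26.148196121134003
22.616771907100002 14.06510794843723 26.496008739670554
22.429758658309808 14.222824359812817 24.290151708166416
22.596367447151604 14.311781060528158 26.128082046306332
23.935024974350835 6.2799020343330669 24.306868329023072
24.145726771520405 6.2763674143497576 23.920580456232585
24.187018546076153 6.146470456568216 24.294054304609279
24.2601300573318 6.2641686542929778 24.975519156224024
22.538077647569434 8.3228588033073887 22.564698595746364
23.856301342130664 8.2651129667140832 21.714202998369455
23.968635062311627 6.98687112598338 22.466185701557542
24.384521894283356 6.4825820095022504 26.186985324512971
24.576052130583268 7.9882033795686791 28.121861682753838
24.314439007439322 8.1570571863463872 28.12752536059239
24.58697800349098 8.1470695275171003 28.239663101296085
23.823042809121578 10.236979168211967 21.487615104141714
24.64601896376621 10.07640080829756 28.960386564361574
22.45451332491254 12.248675449371923 22.557148644108807
23.908502690061187 12.195531874530371 21.806949407356559
22.732361185253637 12.072082212772903 28.107993348961518
24.629458255586027 12.022837359847896 28.861966284340106
24.038078019321652 13.529152818994278 22.425062950549705
24.121094639006483 14.136450235557094 22.909230093881
24.573400290930678 13.735496154458241 28.021748573300997
24.560432679212376 13.99389233634351 27.798655639047208
24.291274350421922 15.048396772788918 24.173435211559578
24.453595359189208 15.122413532776463 26.037550436459703
26.125218024899269 6.2300985642630113 24.116339807126284
26.134512726942013 6.1976055526837417 24.20428748077985
26.15562685793849 6.2282378998029548 24.411554221253152
25.82925833018599 8.2176765861148713 21.715692472776571
25.923275242167968 7.1550932780253902 22.359671133851435
26.326993945686478 6.4830557896580929 26.110230002631496
26.521236204797628 7.966448831796658 28.059964238888757
26.532854966419933 8.1296836824551413 28.182932492818836
25.771402885077922 10.19057729643764 21.41879076046521
26.592472497465032 10.07363000174244 28.966671802622713
25.820300829717947 12.155065443984608 21.705563893184902
26.564992417933212 12.031157405644965 28.978331844923432
25.920442890472319 13.493133992964292 22.322296721772531
25.986714157848517 14.111579682324306 22.779053151841833
25.532345033415442 13.994143695629845 27.996580489840593
26.474348937203818 14.003885026772355 28.107264342347754
26.146479361614986 15.127767381451948 24.108908937450774
26.314646606622347 15.348454989936105 25.992042126986558
26.46358969571455 14.161315256395509 27.974866856085168
26.194130712146674 6.2284618420113453 24.201597992714081
27.043870377119937 8.2111572405097721 22.301593282322628
28.006404866796753 8.2158132082766997 23.30605203524091
28.101388204504335 7.6367314041962429 24.10191204650344
28.305226644832981 7.7401127091592592 26.006154581578993
26.793544288214399 8.1345500074627246 28.048220023669394
28.365883976062548 8.1832854718211063 26.598767773689541
27.794629978557833 10.190118554480788 22.257920124520734
27.863867827988948 10.190981005885737 22.310748415109412
28.489511669845793 10.004161464679605 27.960356307379797
28.492943489704512 10.131109419216022 28.015246616211808
27.348069474484205 12.156690262317664 22.271263601025517
27.875970078806787 12.162662457505938 22.587228285355295
28.461201915261068 12.099159772544592 28.152459277692724
28.020177598166356 14.123558348260532 23.991369821209968
26.8227431647618 14.017008877826633 27.973749503424202
28.428419654302569 12.619558140079505 27.955323427630304
28.289992975761688 14.090394419137588 26.816264153273355
28.028663159096592 14.190382947301273 24.076149414450661
28.208349218038542 14.574078550243115 25.980825047597222
28.547072422938886 8.2161754464209302 24.076426903668981
28.68769155741273 8.1976225692931965 25.983643031563414
29.271026928321383 10.214037373008182 24.038907096411943
29.568308870545696 10.203812734749436 25.937463228706701
28.55286613450599 10.134114554551333 27.956899863786713
29.158007488063951 12.188269577354497 24.047638468030073
29.604829477975304 12.18363023530182 25.946282120185618
28.676136743975896 12.111356997492914 27.948112354273871
28.094380303498198 14.124484389674249 24.075066437105729
28.672301675835655 14.117568330063058 25.975927426031525
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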