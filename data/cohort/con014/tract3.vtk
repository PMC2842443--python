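# vtk DataFile Version 3.0
tractsurf surface
ASCII
DATASET POLYDATA
POINTS 98 double
21.440336037718104 7.4576361105649021 23.923802006083907
22.065217860231339 7.4284489136387473 22.595699604965208
22.111664448577695 6.6848841976387474 23.927152358502699
22.199260595695677 6.9763927000376826 25.944735975885951
21.683039414270816 7.5120761814204942 25.947996435351644
22.245937079034203 7.5390419237129569 26.674970900152701
21.884211312120971 9.2729915870782555 21.850710380335038
22.02634524523717 9.2695261651886671 21.722421321389579
22.034747400686346 8.7680513355710499 21.863336107680432
20.560689494082734 9.3307817859356899 23.895125249240099
20.56317594077732 9.3956478859690158 25.937446413948333
22.365168955008226 9.4554948781937416 27.952796787840775
22.350765942125673 9.4818863980772541 27.952935258759986
22.366535036704761 9.482604653888929 27.963582456033215
22.027250594405231 10.03853096362049 21.828688319038996
20.541990432544843 11.201641689044239 23.849165541888031
22.0286864424992 11.134688036946374 22.011372957793476
20.419891688382744 11.28030917349958 25.908560832820651
22.406539163697474 11.363324122515465 27.920560957386659
22.384854868075909 10.225325948757995 27.948152703911507
22.030997243207221 13.065569551441268 23.799634319786016
22.116563176583888 13.061268719505184 23.692228348008342
21.942641202713457 13.148157856435846 25.870878176285352
22.301864467028942 13.163813271282544 26.259380395124246
22.123184674132524 13.132895721729577 23.797965450338513
22.271730664021774 13.376537519692389 25.86519962260568
23.863990468858301 5.5877752004742041 23.909149783050925
24.115538748863433 5.5794616054805086 23.498168465888835
24.127701036816635 5.4719128725132231 23.904304412896554
24.156599974540139 5.6063519885439312 24.628151365035016
22.560840394831597 7.4157023270677804 21.889079781330906
24.04360603390683 7.3929647054757988 21.000113322909261
24.067793464045668 6.2117340495379469 21.888149151022919
24.212794014861267 5.8799990992220996 25.905044113540367
24.357177216226869 7.4708518329758711 27.899574314598883
24.082207223972759 7.6219709890382683 27.910089298211506
24.369501992656833 7.6350952749393661 28.019967947152054
24.035711859290188 9.2356644481110965 20.683721830521872
24.481102061881618 9.5717756923245982 28.761861901115047
22.376971398739638 11.126672249173238 21.794584117055592
24.051962257497554 11.103140339727268 21.034034837117559
22.445293032339386 11.364567864415507 27.939349001736726
24.526334994523921 11.453656123780172 28.691733221125986
24.086639263492735 12.409935565469524 21.756803560059261
24.115744396205752 13.022556267774602 22.32135862043663
24.486843532981023 13.043004928793513 27.875981495915489
24.471239395610294 13.27459499010299 27.653177198422476
24.198068486697192 13.997679150803037 23.775435961033171
24.335739912224952 14.222817789841564 25.829200132404029
26.152950585318269 5.6008501012625302 23.74655262264324
26.155781596920335 5.5743937159914543 23.840507914277836
26.164939776072632 5.6106536072453492 24.057918641965461
26.083008230169966 7.386104706256889 21.097591461133277
26.097523555589213 6.4101044307388673 21.836082203806757
26.245546587785235 5.9451151984997619 25.822653789649134
26.398466749252684 7.5230782477528422 27.787395270820777
26.411835636452114 7.6922575271733828 27.909589171462262
26.089483820597412 9.2264241207342117 20.724568804935146
26.53163151226137 9.6496828495365694 28.689696477442741
26.123592330565234 11.103586086546304 21.041314151401508
26.583898929313872 11.54996966251934 28.726262979643774
26.168983801218246 12.420804797944104 21.746838005655217
26.198803597467602 13.047325802779516 22.266033228909503
25.531812223304861 13.326492247512839 27.831326186304814
26.544052881983188 13.385613016592957 27.905668773495709
26.27987655931107 14.133587824039738 23.750717684018337
26.398258729378611 14.508420148263145 25.772164752477369
26.535166712573272 13.526703342284955 27.776906939879005
26.218022724242427 5.6045821855319415 23.837706255890438
27.280584298977619 7.4112168799651323 21.782245777202064
28.196588372193769 7.4690968373933773 22.876872064662365
28.219008053454704 6.9688906517798674 23.724953136725496
28.315280235776065 7.196271683376156 25.68084737221033
26.685969142886702 7.6933426354443259 27.765893659747064
28.36214852707295 7.6667877879276922 26.269894446751557
28.124057752559516 9.2788980360629196 21.730911834652019
28.192176167212605 9.2828264278532036 21.789663275367708
28.50374172431378 9.5521975975304958 27.600203467709594
28.511081556225133 9.681045009153797 27.653498834084296
27.708781952092814 11.147661729894457 21.732075133704353
28.247340965128434 11.177381662846884 22.087875185833795
28.568998364744804 11.600378348146206 27.793481836897005
28.35218863810239 13.180732337984312 23.604399723958966
26.918123165918153 13.394521663189556 27.751375701347602
28.565339895226312 12.081858909527803 27.605635911598554
28.509640520118541 13.397026064719647 26.501167138917939
28.357287820238259 13.253295886461439 23.694746520089645
28.46291983476441 13.795869498829113 25.670186434443274
28.698071720634658 7.5238172279939013 23.690796287850144
28.723579255669478 7.6421699645309635 25.644967367241698
29.536144603032341 9.4287132525364452 23.625716690345378
29.719806412389602 9.5822986866041759 25.549720226052617
28.574548989651174 9.6800592781372874 27.593072757597461
29.511372007692913 11.319995589102859 23.630440212107029
29.860451726529977 11.493561137889671 25.545797705279146
28.797805084612662 11.597901823672887 27.578626994944646
28.427919822336492 13.189690847891677 23.691791690132209
28.951614994440952 13.357939664272878 25.634571175565192
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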