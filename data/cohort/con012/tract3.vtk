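# vtk DataFile Version 3.0
tractsurf surface
ASCII
DATASET POLYDATA
POINTS 98 double
20.441231713840104 7.7249106824197122 23.924343095374397
21.21317605311318 7.7595996806772201 22.536086588594209
21.22064650250784 6.9228607300596536 23.914073400056395
21.190437325598978 7.1074336641672664 26.001158587620214
20.59400196820366 7.6616161763382786 26.007224859092528
21.171322473068066 7.6303246654992458 26.760676480971771
21.003139889094669 9.7214634854845929 21.780235979118242
21.166744804281191 9.726561894844961 21.641929424006289
21.177329560032661 9.1951308865957468 21.782485480709418
19.43104826206158 9.650255140229671 23.935313555603624
19.318491256251797 9.5784445867977439 26.025724317452131
21.154578232882265 9.4539591898063193 28.102696578806558
21.138204985959959 9.4806748834765244 28.102661925006277
21.154708360826067 9.4800321613327156 28.114150739809059
21.144050457392215 10.526280375518182 21.766773873276808
19.436942535180098 11.559605829837503 23.929392404211306
21.133508951043936 11.654825896407081 21.985367697164087
19.18422648462726 11.466082211387466 26.031680041499868
21.151601913196295 11.358837884213484 28.088360118493409
21.143607003132963 10.223998123399184 28.105628791841333
21.052445187772015 13.490523194117417 23.889946808329604
21.147383003060327 13.498639073438412 23.777702114013547
20.819479761809319 13.357124466514442 26.006304557826393
21.159376072766822 13.334569281116663 26.401259399805454
21.149823365511615 13.561080201380696 23.88786162381637
21.165373602101635 13.590458115393716 26.002000459564826
23.219077054558873 5.7693029288487834 23.883309983014072
23.51976010137205 5.7789574597627285 23.452209637768735
23.517060330309953 5.6456648191771039 23.878563338205023
23.493209528678147 5.7444306894484578 24.639045296210234
21.809832259133039 7.7793108394861443 21.788090332555448
23.500076105326102 7.8084243771255695 20.817817048815687
23.534345730763363 6.518874969099425 21.759765970128978
23.468825143561293 5.9438098202293617 25.986327060825328
23.424561027866467 7.3957761290575865 28.125266022479209
23.115157926706196 7.5584908569363591 28.120338485159529
23.422081805346611 7.549582486442576 28.25647176933251
23.420897093983413 9.7808925367949087 20.486883255411311
23.387792870529413 9.411237706507988 29.07921716084584
21.517410109982944 11.669004672668061 21.74788968269986
23.348693693251498 11.732389194369768 20.89333453187087
21.191266439727752 11.357527817539948 28.10880553211895
23.349427199206271 11.297212960593535 29.018750582090117
23.310696895616314 13.043817811884454 21.695786700223785
23.297129956970629 13.629211712939838 22.30774186852295
23.314829843284414 12.992715683442876 28.149705689171316
23.309855457987695 13.254911940033084 27.912909910850164
23.286984731894673 14.479650345913452 23.850929352536468
23.291455958682288 14.454698695192324 25.993970455356614
25.719795177072097 5.7544020089370962 23.728712385287846
25.718736558757435 5.7204414403004105 23.829893325144852
25.710609004774344 5.7428372726179076 24.064331305261337
25.713293425290043 7.8144452277488385 20.871317530891236
25.739777873967647 6.7298261218942859 21.672650470798398
25.663786599182277 5.9500109904151923 25.98316452597436
25.610184216336844 7.3558304501966782 28.187046098934488
25.606760229852643 7.511940250012823 28.327895445597196
25.626381974480893 9.8063751668950534 20.464927899584477
25.563752451353057 9.3735417299054902 29.250185465614525
25.52737202723609 11.776839199832409 20.833289985778709
25.510626228732605 11.269891415500554 29.311268775475607
25.459807210177622 13.095329766945994 21.629098029867023
25.430502603100837 13.69312367298844 22.206342386718962
24.396177171965295 13.246082814782811 28.188621299128673
25.441696659810532 13.246705557820832 28.381624186165787
25.387922201110829 14.634082428365035 23.829885077713115
25.384724101174502 14.726140087599967 26.021107835658476
25.435440646465722 13.41011645974582 28.236654115482843
25.783907627258184 5.750652137832688 23.82801739321097
26.952583508814065 7.7922081875284936 21.595167634452132
27.841205875128509 7.7420610682540367 22.813615687860878
27.838106343621774 7.1299477302741057 23.766191573581647
27.775217730919234 7.1485880750124915 25.999851429159936
25.901544587867402 7.5116949308677583 28.200470400985093
27.74553555177436 7.5553032332219576 26.695785600501996
27.707671304706455 9.7872036955484827 21.530369502879694
27.774516305585795 9.7849299553976294 21.595914701100575
27.674186494556146 9.2747520298641213 28.318471051420588
27.670491981569427 9.3964075736793884 28.385104687637554
27.122956160931899 11.7753696087576 21.555027012457433
27.651736977798151 11.766224002238767 21.950489345304678
27.60277729578948 11.314436694343257 28.581081336618713
27.518502528234759 13.658086180658783 23.701294506915456
25.831046735168513 13.25965357109567 28.258725199145395
27.579215769990295 11.837120811817353 28.358417062026774
27.509397539087253 13.386966717198103 27.044825153301893
27.514386386200322 13.719680850164325 23.804928446146572
27.488463524098119 13.950275167694926 26.072920446965181
28.304579632202877 7.6996418422963604 23.751886994661312
28.170256177703521 7.5873955486512985 26.008130835240991
29.021301790041178 9.6842773710826471 23.736909034570122
29.049844588698956 9.5388095032779692 26.049836907842568
27.73900878968308 9.3993530497689459 28.324786062417196
28.826433431458057 11.68027003570368 23.760711754550091
29.043115365839959 11.514470706389162 26.085950260774982
27.846474435886346 11.330121307188582 28.368429233249834
27.58922279241197 13.65298269960385 23.803405685591787
28.0018983264568 13.483040483100034 26.084472768138674
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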