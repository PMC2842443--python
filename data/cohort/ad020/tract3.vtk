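# vtk DataFile Version 3.0
tractsurf surface
ASCII
DATASET POLYDATA
POINTS 98 double
22.538074160712988 8.6061488819872665 23.588294244738098
23.148907197005666 8.5543871089453418 22.341994527737324
23.140908068608269 7.7456019810567476 23.607907443536945
23.253438412330937 8.0690011708010587 25.546996436970694
22.778326243265361 8.6670763116705771 25.53276381070404
23.337789924403065 8.6875469806422352 26.241732855022846
23.11752891869893 10.588302664640262 21.707410831782724
23.256608142028501 10.580990005082899 21.594042092286863
23.22564912229576 10.029116737838169 21.69736294021974
21.789110059312403 10.680677834770853 23.580327362390019
21.75679963738019 10.745898124326438 25.514375717130836
23.539064736017473 10.788024635748904 27.443236792708252
23.52540253792619 10.817411730098039 27.442991425593814
23.541026988251616 10.817770954748859 27.45332302903763
23.316204477380083 11.445779413465798 21.746407388913251
21.865854602621241 12.759181966378215 23.635763092960762
23.386344067417937 12.67037400250236 22.009053892835695
21.664294646275003 12.833627957331508 25.540328410331
23.590391154656622 12.941565521104248 27.418096890860163
23.574248224940842 11.662170909685658 27.434844661804373
23.386462310205058 14.90737186914636 23.799302788881604
23.475536870897255 14.902147685378438 23.70837722257269
23.172722506808547 15.017487093550805 25.620928194664135
23.499431249534098 15.047081925626637 25.971550333293997
23.476272746465312 14.986140535318169 23.808357023404692
23.486656474041496 15.290658360466129 25.637148296909672
24.761716875157529 6.5097681614920546 23.660978840448024
25.000149455097826 6.4950524673065075 23.276568831426886
25.006894615169347 6.3760233377922262 23.669253588390792
25.05522328652847 6.531904098171136 24.367005153214549
23.625278566902317 8.5189226151343718 21.69111762095271
25.047142972172246 8.4655736915312083 20.924072070993951
24.982765269417811 7.1707303558019575 21.735125246695659
25.139970370246928 6.8214586248173568 25.59985862714187
25.40381223516566 8.5314180515310412 27.495552873558829
25.146205812001742 8.7092243229491615 27.488020239864923
25.426473937778571 8.7090279086750328 27.607610651708587
25.192589699304555 10.510036965529155 20.738600760164967
25.623578454166527 10.84948649999828 28.273290783072007
23.729074831074637 12.657476635986001 21.829155081281638
25.344351132183515 12.597727485899922 21.240098855309483
23.628432474307605 12.943049809421984 27.435882214894345
25.660982663992289 12.994739371008055 28.188076447558153
25.42645661966602 14.088491331629411 22.044996050808884
25.446887421035139 14.806908875078328 22.619479741289062
25.547933107508111 14.862693784775548 27.463660722572769
25.521491211345008 15.140041492132674 27.271358292853488
25.431567024403563 15.982072798610274 23.98622340880981
25.407643542422736 16.279368012431519 25.737863966216782
26.96043859665253 6.487164456542061 23.633247055680304
26.961974537415703 6.4568774759665608 23.7238427355421
26.976535863751359 6.498109824827857 23.933953339549312
26.998303500331485 8.4526293831342834 21.15385262536666
26.945307935946829 7.3763049964427019 21.815009706802595
27.095489068676873 6.8428126931105133 25.642716541217656
27.367464907059603 8.5187166895780315 27.528033524330908
27.391721099613179 8.7003750841171517 27.643163866881203
27.142251274696452 10.493091155013456 20.932880423582269
27.600802955141951 10.849427233009862 28.355626469785829
27.292848683825387 12.576152105404081 21.415832410395172
27.64627826659024 12.998985691299778 28.370138868319387
27.369386528892719 14.055712749903403 22.207474638751371
27.383869235217389 14.770702506328471 22.741401429797207
26.530017662703447 15.149224593280847 27.492176609751439
27.494094964925726 15.137213033187336 27.643967960702909
27.34907389938585 16.038348687359921 24.137329013115291
27.310803118172981 16.484231891491461 25.857828339988956
27.47390763401436 15.304805643369081 27.533433167270253
27.023643834116015 6.4894405550711305 23.725588050208934
28.139295253182905 8.4734021374803454 21.902821786192572
29.008817283569172 8.5148885343300016 23.028500077418769
29.003813392259641 7.9472779990869427 23.815281027016205
29.125579817570472 8.147499799226452 25.700915148158693
27.650697294070483 8.6977855585020194 27.530142819043203
29.203780009371005 8.6474104422873168 26.276111214576087
29.046695662440612 10.522754944098574 22.070421847408333
29.109869354603966 10.525058983899847 22.132628253287653
29.438338062926558 10.668542021345068 27.566822348702104
29.449740516950683 10.808268178215005 27.617994553376644
28.754117065678123 12.598635509080619 22.207317544398045
29.244258492761773 12.61127400935572 22.592449607260033
29.515819880950193 12.947396429657021 27.764124274521993
29.307085356223624 14.817457196864707 24.141181630118908
27.852283517191363 15.127906200511694 27.54692019853719
29.496439971077216 13.501818753370527 27.599716172652716
29.372213046874279 15.024863859962444 26.658073371907069
29.306224563454776 14.897310948101916 24.226122646412282
29.313340831316143 15.484609450421988 25.961487222389966
29.482504740593235 8.5418843378730145 23.854785542564542
29.529987907954723 8.6197475371345575 25.72093367304678
30.349296285037831 10.604927603752053 24.000711629580042
30.532078497145811 10.703980203345784 25.818595107324192
29.507716250019719 10.805668460173928 27.57001895827009
30.380238941654486 12.6863440634858 24.146765914603538
30.691953831938125 12.802244021293058 25.922363576181638
29.726895947142449 12.934795149737242 27.602155445261886
29.373345172293305 14.821523312861475 24.226322464908904
29.799624793680568 14.948937864317701 25.971459753629979
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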