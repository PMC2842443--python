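# vtk DataFile Version 3.0
tractsurf surface
ASCII
DATASET POLYDATA
POINTS 98 double
21.530521212619828 6.922507171814372 23.278727572671261
21.988927498090927 7.0246471568270366 21.775675686121076
22.17103565167022 6.2758067903109946 23.376899067681947
22.421804939599301 6.4839482496883942 25.755656347211264
21.92640328298663 6.9335178667269988 25.699112685438713
22.493998957430716 6.9926964319637674 26.620530773656785
21.717002282590137 8.7389655581333923 20.775396316539492
21.839803491326059 8.7616123224683751 20.635937909796404
21.867910990696465 8.2955697655172802 20.831025254563677
20.654827732908711 8.5273109409673129 23.070598965257062
20.807069384390129 8.543052728723028 25.521811418759498
22.533137078523403 8.7687666855439268 28.172582821035956
22.51770748956675 8.7921590864002273 28.171358944566826
22.532299462140202 8.7941476179949269 28.1860390876945
21.826912117117075 9.4511299273577301 20.707495790184687
20.54709238360088 10.209173400359861 22.933996776775
21.818448627183844 10.430342640461582 20.869948849047915
20.542221838175607 10.23960389920234 25.419263883809847
22.387291487212824 10.559216937262532 28.12995019455763
22.477492388131093 9.4906488120694235 28.163679602972213
21.851151063664073 12.098304791878073 22.946694769319102
21.928497424688814 12.108644686304181 22.822697042445977
21.806509984177108 12.14963961091005 25.490022726443726
22.140787130889223 12.2136690923176 26.010191315096737
21.936252400411217 12.172464536458271 22.950992700269378
22.101056778479233 12.404171513367048 25.512912156154151
23.828773879991726 5.3958841348466136 23.529541098675271
24.027446456179209 5.4281692960231931 23.067034640146304
24.079650002388821 5.3055450247778628 23.546114986369425
24.166176428621874 5.4006365277266832 24.383108121489474
22.392791013114937 7.107986307782495 20.99593059425349
23.712205569431653 7.3010521557781134 20.057476072023327
23.830468537453406 6.1213268091394095 21.170778033726801
24.323894167834155 5.6080464735065698 25.884756988309494
24.516523397574634 7.0488367221052286 28.275131824912616
24.252088389057686 7.175032541969558 28.267327277699263
24.522282576849729 7.2011054236737486 28.422950929468254
23.651681808029522 9.045409121233364 19.543059838776148
24.476931878637227 9.0241840813934502 29.357169232458531
22.13175200190727 10.482329173431156 20.63565484230168
23.675528275382501 10.729267743584138 19.833257273036519
22.422535967011807 10.564370965304425 28.157363549157996
24.323935476821404 10.822171094444345 29.291345362778337
23.740622349508055 11.86560399978117 20.633323395620451
23.787938209405034 12.390440780974853 21.292917189629403
24.165125093185008 12.34062093311719 28.261117902422008
24.140982356730941 12.559622129361379 27.975953967607317
23.895025908751652 13.234047202670585 23.059092385243257
24.014132993634338 13.437383972961214 25.641202206874258
25.97383878905211 5.5748072597938192 23.465699540805865
25.985775812244881 5.5435491829991523 23.577403722612821
26.010798939053107 5.5660362247670276 23.830082023176743
25.648258937270171 7.4772259879843084 20.258920715291641
25.740596274924755 6.4823887163887139 21.190593780062422
26.221559399103015 5.7907532309394858 25.91392593432748
26.406351610514889 7.205102415714121 28.286856235937847
26.412318211641256 7.3612683078145302 28.437920558756868
25.602156474897967 9.2511983723928086 19.675606746763819
26.376744022122967 9.2023197995018968 29.425178596798446
25.649794960687309 10.963080991729507 19.926368609251938
26.240911871002123 11.02539074677351 29.491801074815157
25.728101262329535 12.11220797730965 20.71180456030369
25.775589913620291 12.649397209341384 21.324106413708481
25.12947147000958 12.688718407099339 28.285513719936965
26.081008608595379 12.803203892282784 28.454537336669212
25.876766793423585 13.577097219213485 23.147722745050402
25.963918693414719 13.888491357205949 25.714564125757942
26.068817477075584 12.939801297674803 28.289638304163308
26.043465927787391 5.5766563642054425 23.575936680266729
26.839572357064998 7.5391021269070633 21.111870456580018
27.791800593120126 7.5618969489295766 22.456569947701187
27.893478390106509 7.0121376629377803 23.500145752665006
28.111704969858394 7.0897595729997418 25.863108175682552
26.66187728729378 7.3805199308805483 28.282821350404923
28.164882066816059 7.5026725229498279 26.579554466975505
27.607190480170306 9.3824964268839928 20.965362948298598
27.675629389903268 9.3855889737701208 21.039539707286931
28.223725471863542 9.2249795283950018 28.229779626422136
28.221771775192465 9.3451883403092033 28.296867104442111
27.191361292816584 11.090546836125721 20.823592252906952
27.718988315096503 11.12891598334936 21.286154414639938
28.124851635637601 11.175729538678516 28.470758294671469
27.836406020328635 12.866424203920278 23.098125479650992
26.43865889513825 12.833405722673046 28.283479102464195
28.086156361795744 11.645467202252981 28.228409959694694
27.97057257689843 12.93992963329206 26.797534741300232
27.841341710516385 12.928208795040018 23.210851497294886
27.925390504233611 13.344217495728032 25.724701115612195
28.329095182658385 7.5720395909590108 23.467505443477556
28.47415781157477 7.5342173058507358 25.842991393795135
29.054495803605494 9.4336986823641027 23.361222156952444
29.308379412071304 9.4253280276113696 25.766945709404229
28.280543517961075 9.349344038584448 28.226852554759326
28.968501966554665 11.208566987836191 23.276550780949133
29.337935045515689 11.240584560527365 25.723567147218262
28.342529652832933 11.189716952423115 28.217770912326497
27.908511003693114 12.874269427132475 23.213077295559721
28.399053939281202 12.956439818231678 25.720598658344294
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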