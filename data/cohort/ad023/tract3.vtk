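# vtk DataFile Version 3.0
tractsurf surface
ASCII
DATASET POLYDATA
POINTS 98 double
20.413681416737056 8.0776403604529143 22.773695977468083
21.192427021534503 7.985069746472508 21.420752398856518
21.149857346663151 7.2876652149228462 22.88157979480561
20.961477231623366 7.7081216556558871 24.987019136363337
20.384863798635013 8.2701852812655794 24.921017797156956
20.841565913944756 8.3396656916189258 25.710553993591784
21.01166609506668 9.8634273122684224 20.543645972074728
21.169337222684913 9.8616246870821307 20.421346200293318
21.176288578694916 9.3450137481216746 20.580606292901287
19.444916539464035 9.9908785428925011 22.593636123103352
19.137242219613835 10.212491635524236 24.74446724861826
20.558353650253824 10.403356293147398 26.920396129667132
20.541500989642628 10.430999787875429 26.918381572204662
20.555513689718417 10.431903190541775 26.930089580697398
21.139801831689226 10.680628629698495 20.519708736305493
19.394097131408181 11.919529957799373 22.539055264955707
21.112060906363755 11.838445033979021 20.728268054792608
18.934703174595981 12.137630890785804 24.662364773496154
20.481794587361481 12.38069686098485 26.786437554118478
20.512480347915904 11.20958104744342 26.863819720634829
20.870742617674289 13.938841831270949 22.621173938816085
20.972589432393306 13.935434871299906 22.516879238256166
20.412754157617908 14.115887706438144 24.682839806436625
20.690906408101633 14.166494638960859 25.079287890279947
20.964029851292608 14.014255001200915 22.627137407147163
20.745589029940884 14.364527390422912 24.69483727722541
23.047003702610819 6.1660772748209745 23.079596212072083
23.346637955762976 6.1479325874939903 22.670736719046538
23.33205483113662 6.0460126311503224 23.104715418257914
23.27498559585872 6.2154599388658553 23.843839966179928
21.770339668428132 7.9512205200624386 20.725142528647321
23.380386684666302 7.9710776433128174 19.934763668112641
23.394998776889913 6.7531175596447639 20.945709134974368
23.167486403091388 6.5366579480473028 25.156580468052063
22.862345277378122 8.2547180173089529 27.119007917184653
22.549746190265282 8.4258596138921575 27.099381444448991
22.8366212989921 8.4294120519900773 27.232656881694023
23.33209127761533 9.922881178436926 19.517056318757867
22.605084546794544 10.478957184752991 27.864441251723299
21.487795437922909 11.846348031014347 20.52698330229191
23.279355021403582 11.917035693535253 19.869034063928158
20.516858002027611 12.382785356858971 26.806870235878684
22.520925619751146 12.451429109601358 27.680749502621897
23.225504637346713 13.315614710695266 20.645209967966707
23.185484295640475 13.97473207698375 21.243441943274309
22.605848920431921 14.106925233569777 26.802316405927833
22.635991794905703 14.347365044306459 26.576322764657426
23.077402851549934 15.0326667229069 22.750238573863474
22.874824711581297 15.314789641435461 24.78306369179575
25.440667038736837 6.2064165089934278 23.084336148016256
25.437835018534997 6.1784673553535079 23.184150454631368
25.423277665018251 6.2203230461793986 23.405441773300417
25.485021157533311 8.08338306205534 20.220962169205556
25.491593584033875 7.0473984260649587 21.049853783079907
25.30105403567638 6.5792673416337735 25.216988743457875
25.046723755883178 8.2299136577649676 27.164990081637612
25.024270290229396 8.4062947189990957 27.281970410851354
25.445996801724512 10.055207440012996 19.741110441345828
24.818346935550561 10.454919855920796 27.972708147101905
25.397607098830065 12.056866587128122 20.034085698666132
24.728911499698551 12.452314171663382 27.910470796522969
25.345586033118305 13.449086014589168 20.771658598247253
25.310730569279976 14.10758111607821 21.3185753951552
23.723202947299303 14.384060081079946 26.837760329976508
24.799158969562832 14.405609553617115 27.01925573468835
25.207520320924829 15.24710777747646 22.861990477203573
25.036235915399327 15.631207614678141 24.892256738761048
24.814233204969113 14.557767043764843 26.88757738184016
25.500138701022269 6.2113889413920091 23.183804176093481
26.662174856977622 8.1609700611758349 21.033952883795966
27.504272636977607 8.227846961577189 22.247741148292157
27.485205820251977 7.6732663406902688 23.160546388246857
27.370937016783849 7.8629051769817373 25.195807968482363
25.335678461420059 8.3990961788224112 27.159108881641938
27.308586314151349 8.3431449484130233 25.789755869934993
27.439251446513172 10.187373223240581 20.965382085623425
27.503169619870075 10.191797893128346 21.032532118713458
27.120792181227618 10.272332522007014 27.103797952908877
27.111107199763545 10.404813862675104 27.154411415332241
26.940015956410662 12.167825133994103 20.870836992419051
27.451016685820804 12.202168115081195 21.286652695126019
27.029749885915837 12.418287812980308 27.220969948921727
27.340726842661191 14.265185909608682 22.854071504633371
25.224580175439851 14.406290886979621 26.904718429028559
27.032842030063534 12.938600358790362 27.006378497490676
27.114158232316431 14.385249365324238 25.833811010985755
27.334686900978237 14.338187264835149 22.948442723146879
27.187490470196433 14.838518700009132 24.983933356222995
27.945864129784173 8.2625971391737778 23.145116424525547
27.764018777137672 8.3237438694875792 25.182458060264519
28.692447294135015 10.284878415557912 23.078887729013275
28.665602066099865 10.34384544343548 25.118898568061301
27.187595102258829 10.402761157832174 27.10042481817036
28.570569737313793 12.291028440519076 23.014311202941958
28.706375636317205 12.356136380714053 25.063285056683085
27.307154810222364 12.41209997982927 27.032367518221832
27.407747029932544 14.27106692468519 22.951142360607037
27.701262019963206 14.359722866386599 25.003841570112201
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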