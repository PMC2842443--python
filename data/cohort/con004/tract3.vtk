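# vtk DataFile Version 3.0
tractsurf surface
ASCII
DATASET POLYDATA
POINTS 98 double
21.556100778226487 8.6048247690333977 23.585820137851332
22.16494669368517 8.7073448294575631 22.288273974781877
22.227819024273337 7.7472224404795309 23.625548002500807
22.311520654829941 7.8509481432251169 25.621081774291735
21.80087373313533 8.4347519140013212 25.594083191967751
22.348727243675203 8.3731986911547498 26.323532134252972
21.910244377987645 10.842203905274006 21.533755571977693
22.047783146151463 10.850120195375105 21.411620412423986
22.082031455106186 10.278991723589192 21.550698196105788
20.638447493362847 10.678461296515939 23.50488742131358
20.663895050626255 10.478622523004624 25.507871417582663
22.409204803710242 10.234894223720984 27.498272079821412
22.394327200266055 10.262868379503185 27.496953231926426
22.409340018748022 10.261695576623186 27.507559607568197
21.997431834988632 11.693235534209029 21.516614758034748
20.50100716864149 12.714025481450717 23.458182475047462
21.915595143938912 12.865177874072277 21.704715588164074
20.411215773005619 12.4931624027616 25.444074007082961
22.316279673206957 12.237295283959728 27.380105427693362
22.381543755409552 11.047919746894051 27.456719825748422
21.732843298623227 14.680536822564497 23.43560945752002
21.813697873751281 14.690409930007613 23.333889916382418
21.661152156962842 14.444787226126856 25.384740847278735
22.001792398432112 14.391487678074501 25.747015746423589
21.812913917075413 14.748996996576476 23.434417775334666
21.94453509945998 14.674943120948063 25.374913427914375
23.975493781286836 6.5445176473467992 23.681852072009661
24.228515661547586 6.575342363839848 23.27837052240427
24.240187878145104 6.4191517380342695 23.687016462260761
24.259741997004568 6.502055481817556 24.406341881519538
22.652393234450461 8.755080368241666 21.603866262738361
24.11357989821056 8.8070784402169977 20.761129705413151
24.176027383221648 7.4108007800773663 21.660757648855377
24.299775730571511 6.6653603991786392 25.674880109288264
24.384114359794392 8.1113148113149336 27.600955464813826
24.114913889134751 8.2744272480745114 27.593118624856935
24.389748366277697 8.2669521098397336 27.712829594409136
24.003618941286323 10.891134987289595 20.434200647431084
24.400785522362366 10.174040701509353 28.341741668770922
22.249137072465441 12.876552369844148 21.499454430653085
23.869943189611742 12.893529523616101 20.778002460938879
22.352690938271415 12.234626197494988 27.398317533370061
24.297059986749836 12.127134516326754 28.159516835844205
23.772822998030772 14.202602752767836 21.482490789759279
23.732349456474665 14.775004688240804 22.024821647746208
24.088986145993101 13.905032531200257 27.288085067790629
24.046143993175555 14.183037452252819 27.065389956719468
23.695792004478509 15.579092359708431 23.398671073527936
23.79814256247181 15.477990227003767 25.316358212400974
26.267386050607694 6.6055217137836211 23.582244458979787
26.269831486287448 6.5669266523474921 23.677445902874616
26.274466377945927 6.5858353057866186 23.895458370957535
26.145281528480336 8.8137883085560595 20.895506360135084
26.202048225119249 7.6711418333730137 21.649351328207924
26.313061532316631 6.7490316177162741 25.667497650744007
26.357483811992978 8.1428446366308052 27.596972400926791
26.359615671704951 8.2999095654076918 27.712924573056696
26.033552824344792 10.864998484588963 20.497820512414922
26.340822164155508 10.189123391205056 28.394879733682099
25.90627583021055 12.83936587118763 20.786855818881286
26.231089203868326 12.118852151325983 28.306843339422482
25.814874146079141 14.133525959214246 21.458649195925986
25.773124165652238 14.713028002387578 21.951974051511986
25.045742734925298 14.149575541579333 27.261709850964078
26.010993448799752 14.13304550425052 27.377697956943411
25.717196394687157 15.609655042198725 23.354085903643565
25.766420280392865 15.657982928933185 25.266724052052812
25.988014745073635 14.300106935624823 27.24379213038964
26.331666134522411 6.601342042412651 23.675874842838077
27.349920005928862 8.7943093608918677 21.601852861222298
28.26513548055317 8.7454436085752985 22.730067244263676
28.301759140866437 8.1063522362018805 23.605344932358435
28.333854723121924 8.0795042003193185 25.604491325048102
26.629717640092576 8.317073749510147 27.588058252711328
28.333439613942055 8.4816919492636593 26.197824545650747
28.076513255755096 10.799042594754868 21.523290474962661
28.144963769905576 10.795547403488504 21.5834804452311
28.296801698416644 10.190958978231675 27.492360730637767
28.292182104179918 10.312011313185062 27.540489982774702
27.487692889513934 12.760133913607278 21.467449565608884
28.028201383351071 12.726017461286123 21.824805434062444
28.177733728651511 12.227423663762901 27.565140091099977
27.908587970911718 14.540399060495695 23.256440284927201
26.373975195534282 14.149859853360358 27.250512497903969
28.133124046917011 12.749550543141369 27.339656020566082
27.975290909294603 14.277979033954994 26.130559117053437
27.904546390213046 14.599182792106392 23.342650120066864
27.909530301817096 14.821330558861357 25.273993154483794
28.757781235016477 8.6977704285474928 23.578172527525894
28.719970884397441 8.5427333741462697 25.583208686619404
29.474138384307473 10.675941265533918 23.490091394431804
29.588513667046421 10.521722430262384 25.490564550315106
28.35712643475981 10.318681964847224 27.485579765923525
29.279119072530229 12.599572778066356 23.407892210595271
29.563294268255049 12.444090659172291 25.393003924651765
28.411808844077051 12.250694760127228 27.372377362791031
27.983230664555567 14.531342808818843 23.343943440364594
28.452046575108653 14.355446622231987 25.294142044137487
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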