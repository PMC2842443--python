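# vtk DataFile Version 3.0
tractsurf surface
ASCII
DATASET POLYDATA
POINTS 98 double
22.527022471170625 8.4729864947848768 22.648846019125898
23.223668008550529 8.4460525949950522 21.424151010639612
23.103927313222528 7.5430811933304831 22.705479522780664
22.91505145057636 7.7317295031344724 24.721403436623692
22.452230992363184 8.3716592002831121 24.672540660391302
22.83721511569188 8.2920262680982191 25.468494006285741
23.176483458428709 10.608858504519409 20.832865387053918
23.313006565056167 10.597564171853763 20.722706909943128
23.300870195530706 10.013884853978851 20.807712116351169
21.756392993628111 10.659360418801741 22.678979487892356
21.419344927159525 10.555285937597333 24.665494342432087
22.664381894560485 10.282793601720972 26.856883566613512
22.650471502423937 10.313369865405772 26.857079054422496
22.662628735855513 10.311674275043638 26.869764962952683
23.311446198822757 11.486962386442483 20.910562030569494
21.70605064973763 12.767702414079661 22.8853585718829
23.277178273151616 12.735809724842198 21.235959215096358
21.235454321983717 12.66270772941675 24.855150529911413
22.657223271849119 12.437058674202881 27.000591543451243
22.665461171991243 11.152970922365945 26.912262499360349
22.973669931811127 14.793620690794146 23.22872395929658
23.065299775553768 14.794112638937387 23.13117035813551
22.563369051908634 14.700270675811639 25.20339990690016
22.821747387400464 14.666277145105081 25.603216783396611
23.052264082635464 14.864284415788884 23.243053558995783
22.852436025654338 14.941728315690611 25.254654553330095
24.626483477922932 6.157214718883071 22.908184492818066
24.886845050218092 6.1389568688919596 22.530952573039805
24.856929546066244 6.0041881832533059 22.940710732558742
24.81897349055518 6.1231392890252536 23.665541801016076
23.714959735303406 8.4031123260236669 20.79654017563994
25.068075235969786 8.2464315257707312 20.095666276960909
24.98464244878857 6.8850710018839028 20.93644957365807
24.721229190036304 6.3457530011867505 24.962753125306044
24.531992931660326 7.9082385247723419 27.019290878867185
24.276952899550661 8.0987227661514183 26.987367983261905
24.51820758549961 8.0751437510530408 27.146639646613906
25.138510415893453 10.398659198667652 19.904202129512456
24.429680898064618 10.135564252621666 27.981730039580562
23.606283615391892 12.713952017217302 21.05248512229948
25.122761367528149 12.576146081506039 20.440206067089548
22.688863103700882 12.433855286990374 27.023374273836524
24.436241472776938 12.278140653744543 28.040339567862905
25.041117770066535 14.055470058486991 21.304922391562364
24.976420520522833 14.722232763751764 21.930919842338056
24.514350999753919 14.204864145480601 27.371130683512039
24.532861264777388 14.497274759852832 27.173934520820957
24.821928790848016 15.712024841856298 23.464140328629174
24.661795003415815 15.774893139574983 25.486915395939125
26.681620494224582 5.9657732305326725 23.052815117951045
26.675721430751505 5.933439773653931 23.149011681207018
26.667377126447441 5.9661044391503735 23.369795906589776
26.841001678320314 8.0287659453208953 20.413690537536912
26.784204313336762 6.9098050741791726 21.128610260241299
26.565355130394288 6.2424123294782392 25.186592324717004
26.413040204799881 7.7937101126483945 27.253232609456159
26.401432496568102 7.9653920413681547 27.384896103236752
26.899622874510417 10.174504057295861 20.132902397517597
26.319541417048629 10.035059084610308 28.266424034152017
26.881957232378699 12.376031894253737 20.597546121561177
26.304480149491528 12.177284496553659 28.406785547130585
26.804963722522182 13.88595329756615 21.424264676051227
26.745358113289885 14.580239078121069 22.002908138402216
25.455948435417532 14.440834832909079 27.48197462526452
26.351241734564343 14.3928425010174 27.698280559738617
26.594419729069919 15.707687432285191 23.588944676779033
26.455855665022469 15.932073907834219 25.644123614209299
26.358069513590795 14.571646505425816 27.578834343432096
26.732305215345043 5.9610237223425857 23.154368302979712
27.845204562850494 7.9218787569042215 21.23646095061337
28.573127181296844 7.8664775777330673 22.464485340935187
28.530402840389883 7.2771251066965048 23.330365932918731
28.432572916893097 7.4239839246309707 25.383192596058304
26.674734400184526 7.9562772758685272 27.284714861972809
28.398769982811359 7.8961068808448998 26.018175651018968
28.571788235256481 9.9865512146387658 21.351334555711009
28.625998117616835 9.9817159944944436 21.418679814821044
28.293646357288711 9.8462141843565636 27.499907739528538
28.288060539905366 9.9833397753547324 27.562011946441448
28.164367443664663 12.235315738204127 21.418779713471032
28.589256447288932 12.194103251252683 21.831301435350039
28.247684389792454 12.131803780340558 27.799451443412366
28.428078745861541 14.434052954697671 23.530378753017654
26.708294090343713 14.384813286923032 27.596157672945328
28.25043673173677 12.708957147226412 27.626209835032306
28.272976207573155 14.370040954573582 26.547249932304588
28.41933857457952 14.510114511302074 23.628908163875902
28.293890719297025 14.930028645448074 25.710898946636057
28.950841150191174 7.8475538010745991 23.375281765889657
28.79287692388662 7.8757826114831646 25.42257218738321
29.642372390860331 9.9211670497671207 23.483266340762452
29.62652364021621 9.9433502466791186 25.545920888320587
28.354093763410912 9.9820155360809402 27.510355899491937
29.532232797016473 12.124747890429731 23.567397374893005
29.658234320604237 12.117021898758519 25.642205199392894
28.482552830433033 12.129320903917002 27.615665801842805
28.483931619101249 14.429255245268461 23.627992294388779
28.747526067653052 14.375779870637846 25.707140324593972
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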