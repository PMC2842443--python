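# vtk DataFile Version 3.0
tractsurf surface
ASCII
DATASET POLYDATA
POINTS 98 double
22.202914363983083 8.2834217694986094 23.855673181300563
22.85328415776776 8.2868211257013655 22.583410562221076
22.894334169967983 7.4327214635713084 23.828874005168871
23.000456786750121 7.7154902876497218 25.795906849498202
22.46155837094048 8.309922955073592 25.811881723924785
23.049563006352727 8.3236424159429419 26.535062993689081
22.698522157855454 10.382411378558306 22.003987932842421
22.848857340567221 10.386857083686284 21.88175209695757
22.849740794180729 9.8145856897920378 21.974257005052483
21.287700332818837 10.369315818286244 23.941995552773545
21.260489925168233 10.409538826526493 25.891317249311509
23.112347097735761 10.41948321163626 27.910577391667356
23.096320191778204 10.449160109454589 27.911953657509997
23.11242102104066 10.449311024167525 27.923225821565055
22.860244179811144 11.268626502393646 22.05986312851924
21.251878282802259 12.484413028303925 24.06598157913545
22.857110955124508 12.521479019696409 22.352450503873559
21.057960695265574 12.524294737026564 26.012322159499462
23.076498523521941 12.57085178591929 28.04807943316349
23.107853965867136 11.290309650400786 27.97364080416996
22.77218547986369 14.701314318942948 24.270993420967326
22.864948609659773 14.705922449438521 24.173115015778968
22.597346675297388 14.699304897340872 26.222428423495195
22.954880243119753 14.711596003758171 26.613376387396151
22.865615264880763 14.78477303292579 24.28039060175908
22.930083727089126 14.974283689434458 26.255768104368855
24.701450087857836 6.2488781648770306 23.799371689577448
24.96195927415782 6.2570031675366096 23.402275989120014
24.972627960230124 6.1257578241670565 23.796529146289384
25.017537484614522 6.2576835939566315 24.514009810478285
23.367759670676385 8.2972632376701334 21.902978641215022
24.931201059018157 8.3531782510724177 21.045863886580506
24.916425329246888 6.997506560569402 21.849404627872978
25.08322749109394 6.5149975431644052 25.781831929529211
25.215789629822282 8.1811542259943835 27.841310386870429
24.932525846409572 8.3520440569013203 27.842411149649088
25.223432948630215 8.3562556154198191 27.971826273844471
24.977871741195262 10.476181439927661 20.885232953697297
25.263996208942029 10.469337691546292 28.868224201802256
23.227049618639683 12.537772181999216 22.150434559568485
24.996310674490839 12.628008421614105 21.429504447199875
23.116210363083741 12.571254782667713 28.069030415925596
25.224368786123051 12.591376649891606 28.983145100495374
24.982190073633092 14.128216665231337 22.296733640367275
24.969454972490031 14.827291886181554 22.922476196876438
25.131429957002087 14.465583267226043 28.324204963854292
25.112150215995818 14.75123967315157 28.123830176122198
24.948756969302561 15.906569832592313 24.43257150797518
24.995392583267154 16.017801932710427 26.4177896396459
27.111620933991595 6.3376915241836258 23.711950333261381
27.112427347202733 6.3036421742790836 23.804636330820362
27.124200560666051 6.3358733481358662 24.02471157232597
27.115166839350465 8.4652835959901864 21.1628793797443
27.090596570362504 7.3243388992246032 21.841853201002049
27.196987086524011 6.6174246202654743 25.815568234089987
27.306974912673539 8.2293716465338207 27.911977879356321
27.313509438234675 8.4066190646979564 28.049872486546974
27.167542786951408 10.601906705687032 20.936602962929154
27.344109915339814 10.511364712159461 29.027484482624875
27.173536746642601 12.757529731468001 21.446761690065191
27.297076093608926 12.629270229962515 29.259826837714513
27.136089418214326 14.247461607221624 22.307390846115062
27.103513550407786 14.945907315756282 22.900130816765735
26.173637492288712 14.770810026248762 28.406168484914168
27.179998961358361 14.788333852121792 28.590676572701476
27.031057857620411 16.107673905448507 24.490194086009488
27.035482160602584 16.336399218150255 26.519261003369319
27.167207064690665 14.963997119173909 28.470644936744094
27.179701430948146 6.3399342259103584 23.805855796960714
28.397079637796971 8.5426933576716841 21.876824179793346
29.353009447640481 8.5952784561668345 23.032094026699308
29.337658003404343 7.9624117264379102 23.870719158983427
29.362327787438087 8.052780385330589 25.919029623771639
27.600082331076258 8.4180751884446288 27.934642834247391
29.383696062259922 8.5224790928312295 26.576907994476901
29.312213155229134 10.741574436123093 21.991227447234429
29.382490727921883 10.745997287152685 22.053819324553
29.400042036894355 10.467325708838096 28.160972081241546
29.398094185884151 10.603244764222124 28.230306548313965
28.814144675198953 12.856855783035337 22.16586412056499
29.359347171127453 12.886398621781387 22.544147819108993
29.342870970254701 12.715544727114068 28.5766015919769
29.231784973611607 15.015916058538512 24.32100986600738
27.564350854835219 14.804341835115814 28.481165147151724
29.32132071301433 13.278830786215334 28.427138486646328
29.228391351004973 14.902926217011704 27.375839068174496
29.224950972128919 15.088169795848128 24.421368409465835
29.181830053835611 15.461269252909037 26.527612558667077
29.849816014088368 8.6123969837745484 23.903365804074248
29.784579161471608 8.5592019469703153 25.956489895129259
30.70519285336233 10.803148969752826 24.046585071821447
30.767345814461621 10.741887623559291 26.135941628701044
29.466062493284575 10.607815570890432 28.175763149936031
30.578458083195244 12.925235575925615 24.226278373208885
30.800005013708535 12.864697719826946 26.328685516693739
29.586869405109638 12.731925463745799 28.38294497416052
29.303511134153609 15.015947018700409 24.415276746051941
29.719515429187325 14.955041187356322 26.499765608376052
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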