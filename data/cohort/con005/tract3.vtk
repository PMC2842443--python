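# vtk DataFile Version 3.0
tractsurf surface
ASCII
DATASET POLYDATA
POINTS 98 double
21.738901230599744 7.9699122705124754 23.877455015177173
22.36346346861616 8.0059325599957631 22.630842353594765
22.348585088942176 7.1367948360832818 23.902699512930411
22.432743970013263 7.3185451904060983 25.818544817534821
21.958136341366732 7.8876746549642887 25.795863579338132
22.495313751169281 7.8525579536770751 26.497939055540716
22.298582663555223 10.038745338556247 21.93666550371147
22.437198307956233 10.039428696839488 21.820054262999403
22.419071977153962 9.4915190066734869 21.946420270722715
20.972172428004587 9.9806440160918868 23.826457086326087
20.9394674169761 9.8767160232720279 25.731387612887048
22.638820860084572 9.7182728122183342 27.651854468357485
22.625321301878614 9.7456867532728655 27.650758346002032
22.640069791357341 9.7449780150183134 27.661290854053444
22.450641748509156 10.858184506253901 21.934462628764862
20.978723752727959 11.962776387687944 23.788009565372619
22.450164724888001 12.006640609307389 22.123980656899946
20.796280253842614 11.844438790321799 25.686736371813797
22.623203496910495 11.679697750072991 27.591523746428031
22.642893395991102 10.512464617312679 27.633742637360324
22.269120391656774 13.860010579753311 23.796534727160939
22.352279549914993 13.862279587632329 23.701353256947211
22.096619000703058 13.741550178955992 25.687412433436037
22.411162516013182 13.705853713947686 26.055751908043678
22.347465981054082 13.925186675389554 23.798721891985565
22.375585796404611 13.96330389135816 25.693886663621718
23.987406107433802 5.9457555150229737 23.953816361643504
24.232822403147431 5.951400328932559 23.568472314056606
24.237305093649766 5.8186030082760194 23.960773133041759
24.260022551003271 5.9261476863171305 24.661378511056157
22.85672472396093 8.0183280889342541 21.970222965864298
24.285348275457689 8.0024375300513988 21.177564239097592
24.239442959766897 6.6934518516621972 22.014030013376345
24.315215047155625 6.1391907691009386 25.888817377329026
24.479151431573889 7.6313138247779051 27.768443156174644
24.225126085911739 7.7934473137115505 27.755039085951648
24.492430894881835 7.7885653449942316 27.879160280864266
24.342287991427202 9.9996818923763069 20.923617317871454
24.584584896230204 9.6896366027206131 28.537496100058913
22.779686181543898 12.001722025528721 21.935692557535504
24.337864693483954 11.952966307358484 21.30787015187466
22.658705603515347 11.677906184120925 27.610505816791417
24.547192693216726 11.606950548744553 28.438058799174609
24.271921356227743 13.252202923066241 22.010468359909407
24.219477766444321 13.832381592947316 22.541115320181213
24.382494645707773 13.308194671985671 27.662101990808985
24.345319544763846 13.567180084966708 27.453934896999954
24.118499936634667 14.689535701089003 23.88143297204515
24.139231915204373 14.716920512595667 25.765163232582779
26.174750023368642 5.9195479774127113 23.92634295656039
26.175949917795013 5.8870734534355549 24.0173394024612
26.180983005539911 5.9146420154560113 24.230294989241898
26.193445625812071 7.9356310205021439 21.394473548690616
26.172283240642244 6.8628351935312244 22.082599690520567
26.238550053700905 6.161254715411272 25.95035599120035
26.363880512600286 7.625249445929728 27.849334539200466
26.373961968281371 7.7857323770070783 27.9657005189827
26.220070894902673 9.9075677544769736 21.099692507130097
26.436038752064302 9.6839370596228918 28.691352720481408
26.192517503872317 11.842768100645934 21.462467710544331
26.386285309532731 11.586368999391084 28.695139167052861
26.116846531537576 13.133146395375995 22.153701106341813
26.061939079941986 13.721559237589609 22.64368306070266
25.28951641124879 13.535303805734888 27.71114421829208
26.190633362703213 13.513482262999066 27.888377148329152
25.944675873483622 14.675084776766015 24.014849962683474
25.942109137888071 14.854965038409691 25.878012124857531
26.167376884847464 13.668473240863158 27.764971487378247
26.235425500664562 5.9173805708884313 24.019454847800567
27.293826823995325 7.8895094964530061 22.151052746697488
28.119447309716591 7.8543284228021637 23.297566481087419
28.128089363045827 7.2817354268043841 24.108051175762075
28.173727881876818 7.3791887126906257 26.029747495659269
26.626375513051691 7.7886990080447385 27.859678568853958
28.194835995079302 7.8112832352626871 26.617376168950731
28.046642613313274 9.8090512719056306 22.245665262760525
28.107007167966152 9.8059535143962897 22.309004989403608
28.238044970950682 9.5840073124651433 27.934264251125889
28.23817099271724 9.7071074007227676 27.986009098552739
27.580099635175397 11.749607835454208 22.261610593438593
28.049708827793474 11.720918569679412 22.654188623831882
28.170360516501663 11.603764009279338 28.107041313392177
27.905228484360233 13.591080396328701 24.104833448962896
26.522769079046739 13.513050895708725 27.791618338875026
28.128134507894444 12.103481277782546 27.919187419700123
27.955290780192932 13.524870090775297 26.837323263746796
27.898706241063469 13.654370277509138 24.189048263609031
27.879080870501376 14.000614156269526 26.039329335084691
28.568831424358784 7.8374334872668605 24.139557062110029
28.545039130498669 7.8171917973696212 26.050919875344896
29.279458552296308 9.7515183674552457 24.227922686910023
29.390294383722043 9.732694130158313 26.122781594529648
28.29689100205686 9.7082121472708103 27.937496263399723
29.130172286937981 11.660501645671696 24.26711819334605
29.385399200777659 11.634161750235268 26.150335255348732
28.379300286464854 11.607779935136579 27.938650730592947
27.969214002163998 13.586768797622943 24.195138891410966
28.371736150673183 13.535910262256371 26.081963437672638
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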