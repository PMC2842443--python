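# vtk DataFile Version 3.0
tractsurf surface
ASCII
DATASET POLYDATA
POINTS 98 double
21.405867730260088 7.7223455809442463 22.827838852748119
21.965236079343583 7.7057037325772733 21.556943594728288
22.020481673943532 6.9484830099522874 22.944333241743969
22.109614570175836 7.2112637563800384 24.979743376532358
21.637247024375089 7.7543950196473084 24.899425890491774
22.149378694796503 7.7657742731234904 25.691022129558576
21.80084646117859 9.5647619622722999 20.718835848212148
21.929536959475957 9.5648118468726899 20.606072119716529
21.935119999328208 9.0598160677596979 20.760899204612397
20.63632491722645 9.5966323050049205 22.626746759898111
20.653290626770197 9.6490739089578152 24.687504502219447
22.23795197397693 9.682816807099158 26.910925530161929
22.224941741958361 9.7099901054704993 26.908598579147096
22.238880903495708 9.7102420552667024 26.921072405026976
21.937199110025784 10.353026868558228 20.686340827680294
20.645986029637616 11.489319828130499 22.554396119639115
21.947813639696143 11.467500081263564 20.861413440299106
20.556297721964526 11.564142726894779 24.605727771096443
22.269603476880452 11.675496693078614 26.819141435194169
22.253775452723826 10.489304514894679 26.872142051223662
21.962533404859116 13.479306298165888 22.654890510020685
22.03773919939659 13.478232859214961 22.555142517070568
21.886813226577218 13.578901438448316 24.702717763965772
22.196718095262511 13.612703168706181 25.119411563753577
22.043615286225428 13.553823695254623 22.66287623861961
22.171727349292055 13.833825359343711 24.730151666270334
23.677656551891879 5.8456465874837988 23.158661122522581
23.915813601014218 5.8466389973586139 22.766522176718183
23.931759142291885 5.727122534596262 23.185525891304035
23.959307186626621 5.8516583178274182 23.906487223305277
22.418242137928523 7.6969098768316577 20.907566239815438
23.813348112684562 7.7143057008052516 20.17219869441271
23.851876131593464 6.5043324068677961 21.118597096618696
24.009652017608445 6.0833468580063226 25.19484796571064
24.096406247927991 7.6027376926512282 27.158041884524145
23.835004029243645 7.7663809200835878 27.132352280364479
24.102056087547691 7.7635051003830498 27.274285350045627
23.801501297256383 9.6077272402970859 19.778157682245148
24.139175942863371 9.7254233336891751 27.957161450572432
22.26301242874003 11.474797201050103 20.677287624628541
23.817338202834936 11.529700524517152 20.084677746291675
22.303287873366337 11.676820761089697 26.841973003066581
24.13444616935103 11.721734155827752 27.833287518074386
23.836029577654219 12.882853371380973 20.801027634185758
23.848317269408636 13.524459809338747 21.36967054128316
24.08778075525732 13.471862973037268 26.97484287404373
24.075062661567358 13.731887242546053 26.745807901200461
23.885714692974965 14.559914171552229 22.844281108820528
23.973525506941009 14.80301284971249 24.904225233782867
25.883371311964275 5.872881259373667 23.191715943426733
25.88706993856724 5.8414611138973882 23.288766090072095
25.894575365124588 5.8717512299776011 23.506083636052999
25.782246787952722 7.7870635677534814 20.45026576344759
25.810581720058959 6.7620023528644246 21.230806262999064
25.96009038689931 6.1223605576077524 25.292489057739427
26.031284233276942 7.5908650897728016 27.253542013208229
26.035104505294367 7.7541572223737809 27.374045464907429
25.773756955664787 9.7078839281970453 20.007470369019611
26.045058208770104 9.7209814895399749 28.123523930288254
25.787681108512125 11.652542027564458 20.280817528766999
26.009739369079089 11.735168157067587 28.126566016072953
25.79284453676323 13.009388023291566 20.978180206705456
25.790884688492945 13.653302501324442 21.503580444564783
25.01698954479026 13.76092167839696 27.051849375804291
25.930910847633069 13.778051545173886 27.260505488252225
25.786027095391013 14.768588495343504 23.019536202251402
25.821659652615484 15.113200358557114 25.074420372050483
25.922006498856497 13.94014826976044 27.126797022463339
25.946672949773927 5.873050796887842 23.289552290053692
26.944051568095684 7.8375339896282945 21.237418348808799
27.823210056452425 7.8662906325716619 22.422902339456705
27.85358351977434 7.2899446828741823 23.306103456802656
27.919346372547444 7.3689223153031236 25.312979115737743
26.299119346032743 7.756866095959726 27.256276787632714
27.935202720174207 7.8001427125479168 25.910718664541356
27.727451300588065 9.8178492995797217 21.201989657736927
27.792011570405482 9.8211321099401374 21.267639655401467
27.949810180560572 9.6131062938010103 27.263173785162877
27.948550799384016 9.7415911913643374 27.317282815340363
27.288444261541194 11.758442894503844 21.115900082233154
27.793065483666979 11.789765224039865 21.528119222520608
27.896107056944917 11.758277328489783 27.441432530754287
27.770373562296015 13.796848460005767 23.069205116600916
26.278059373361224 13.78496519600281 27.149886872116586
27.874103217518552 12.296183991322753 27.238708860867693
27.798957242946347 13.815604332575552 26.071399691842988
27.768716186762131 13.867257729891564 23.162674702562605
27.768155058630313 14.306441148145936 25.207445274431308
28.300911199950185 7.867003551407759 23.303443925650395
28.295608971805844 7.8208091381245843 25.310338053377993
29.04114527134498 9.8597488156794633 23.275952469551903
29.163709397447004 9.8192547350626818 25.290654225841589
28.010787167171014 9.7436063041253647 27.263345912327232
28.943504884944982 11.844074332620812 23.23781443337451
29.202810904162966 11.825646100021224 25.273584480487731
28.119774158116297 11.764761939317799 27.250913492102939
27.838224219672004 13.80090939674348 23.166911610014076
28.249567325339015 13.826452461281797 25.231646378393766
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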