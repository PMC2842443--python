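# vtk DataFile Version 3.0
tractsurf surface
ASCII
DATASET POLYDATA
POINTS 98 double
21.577223144360172 7.7404654448668389 23.780312863137894
22.258817208072177 7.8113130600210958 22.522136042299181
22.215334187451056 6.9560622916653472 23.816386505580812
22.167255727400214 7.1824356942572471 25.827790296257614
21.669267526345639 7.723195489125608 25.800718751286176
22.149038848400313 7.7474970430661401 26.571899375236203
22.138490153217941 9.8348325269699952 21.857236079432255
22.282155573410268 9.8472098296902484 21.740839420935121
22.282002895445217 9.2953167557321041 21.853468451327476
20.744296314517953 9.6953154135785251 23.759918078823524
20.585331612899679 9.6661285933717753 25.771386649918856
22.084578971170547 9.7214388263972449 27.928428090688033
22.069723957428575 9.7489828813551309 27.928534717953639
22.083489906117226 9.7497187223333732 27.940617896452267
22.264334107565084 10.677788482260258 21.889599901124139
20.695910429549762 11.730301144358558 23.848207813427802
22.227018878513537 11.860897813605799 22.151195172306551
20.394069572715132 11.692626433931302 25.859456235628034
22.007253032519984 11.763064774128678 28.008497501388423
22.058904853862142 10.543773029307426 27.963333775829412
21.983361911167783 13.854853310148677 24.084078225108094
22.072541600734223 13.860937458983637 23.984158402193611
21.676076843199894 13.804557527812115 26.099957376921914
21.958123875142569 13.809461057458678 26.504422753640327
22.064058102167824 13.932509425687947 24.095168055721874
21.960430600845033 14.065789962130678 26.138243930707524
23.900249561968216 5.8696301477119199 23.906898742797129
24.166443431383964 5.886961837380575 23.514786435793006
24.155954662954034 5.7555978337814473 23.919096034529147
24.141280229512713 5.8682241147888696 24.646070424236967
22.780083194427505 7.8618651511835829 21.862936220097769
24.259807347226353 7.9540147976688971 21.072840397441066
24.219539966516372 6.6349144857057887 21.924661312353354
24.118674304072275 6.102306069630103 25.936466030848567
24.07622081644411 7.6775887987546021 27.99809586515515
23.804393978642132 7.8310990582633018 27.984278239063922
24.071736639051775 7.8435127999487868 28.125766728945635
24.26127447980484 9.9692876155235854 20.826504451583993
24.005836724812909 9.8396780204043566 28.956738194225306
22.56900384939815 11.883762868542435 21.957848465941492
24.198630081554445 11.970375423608701 21.28405115920955
22.041050938303879 11.764442348022161 28.030480784296287
23.909647598331869 11.839088829986594 28.984124827129325
24.109894857715918 13.337613207904301 22.10986477992202
24.050171459919635 13.964822100838735 22.728895450176079
23.815039766719938 13.595101171867201 28.259186410947777
23.803306749889828 13.860531633788296 28.050762858415172
23.916229310519267 14.928682731310037 24.264101282451612
23.798383421136638 15.025173599848253 26.305036377998821
26.125188179627557 5.943428600537775 23.910209147882739
26.12331200906608 5.910916835201121 24.005075519523601
26.119446822745246 5.9394423256687396 24.227180811440906
26.202520737619484 7.9945400545953405 21.273755013108531
26.175994619889799 6.9022169713909065 21.994824037825396
26.093940440621417 6.2076057116510839 26.04107341609242
26.060188269276452 7.7514332794346714 28.124698506946554
26.056174815053126 7.9205918915860494 28.258118984215237
26.202136319353283 10.00431718313928 20.953008684156138
25.992117712459443 9.9160313873603165 29.152185049443553
26.142956558476911 11.999737042503039 21.357487803161085
25.889826852330788 11.909002068002708 29.276348166850067
26.056844251962879 13.358652345341943 22.154817006422768
25.998768130140231 13.991845441649915 22.727231746963238
24.790106594828515 13.888418030215009 28.32817270217695
25.761865308668426 13.915709180317101 28.508791882953634
25.852973412371043 15.051449223235899 24.313616273054354
25.729113050697293 15.297103830446197 26.379842010124449
25.752412919113798 14.07649774787833 28.382171249616295
26.183443600952995 5.9438447717977354 24.00772404166732
27.304274096387413 7.9922591530606297 22.034996937622001
28.119060411725609 7.9866581545439068 23.226562505333877
28.107424496057021 7.4029530893775188 24.096941973467768
28.087102225460441 7.523415496404084 26.164941098365208
26.333927179866766 7.9295147913066799 28.146951795067174
28.079385778273771 7.9786407152257262 26.811236062892402
28.065154692177039 9.9944147937761869 22.075064965159946
28.126308129390871 9.9938617905392846 22.13966607458239
28.033569601679712 9.8495817814060604 28.31674178558119
28.029123511942796 9.9795147058845899 28.379201789134079
27.586109347036302 11.987245820234273 22.111819338223665
28.072679648571143 11.982711480917439 22.500530508542813
27.94094122327278 11.968497064604456 28.595367455622174
27.929922606501826 13.972714365033907 24.161005307559467
26.143209103594899 13.924651447354146 28.391038468495051
27.913216100495209 12.48741084647653 28.405652182846872
27.835228594461444 13.959388087462084 27.245858887991186
27.92226909546093 14.041788035866469 24.258765526087792
27.822433612144643 14.449698041106904 26.366549040801011
28.559999433964229 7.9889904303221897 24.120659780348475
28.473555503272312 7.9873304660472826 26.194161097566198
29.306823496774449 9.9924975671696128 24.171245385349049
29.372545892221229 10.001575932801391 26.280688432969139
28.096768291037382 9.9812151021416948 28.325085439490046
29.182925328068716 11.978180402846366 24.200516903004747
29.400386798509643 11.988875581502228 26.322344669907832
28.18778636224042 11.974080158042646 28.40007607166773
27.996004478845087 13.972158963445816 24.255577060939025
28.349106497742397 13.967352246565966 26.354539404444242
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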