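# vtk DataFile Version 3.0
tractsurf surface
ASCII
DATASET POLYDATA
POINTS 98 double
21.114605853412332 7.7417413276300628 23.480959636043842
21.68139374695706 7.7620192371343641 22.212526672990528
21.842816328831994 6.9598627022133428 23.481541061139847
22.016782920877667 7.1849922500806009 25.34569328923747
21.466168841675568 7.7277238326835231 25.33259761059049
22.065232662961293 7.7198242291037715 25.993019433900681
21.324392753818316 9.6515037438562477 21.522263320812684
21.463850476554285 9.6556970989195516 21.39138685266925
21.516316853215578 9.1473708630172634 21.517589099873589
20.070343524058991 9.605365800930505 23.489719776912249
20.18631646572911 9.5927514346871394 25.32023330769325
22.110575217843817 9.5418205321616956 27.092300793310603
22.09417574590746 9.5677203218772426 27.091755263794248
22.110372407611479 9.5674275530723829 27.101468911846098
21.410841718916405 10.410456384049258 21.507395007734086
19.896871428757073 11.413298642931318 23.49630231895993
21.348916800940781 11.459248840222635 21.71532691779862
19.872833151305962 11.392622279212715 25.328797307186324
21.996631409842102 11.350635836147994 27.050039097832681
22.065462090942219 10.279762898651203 27.075214797993134
21.337184991940617 13.134938726569841 23.433058265333251
21.42272685150197 13.136553649452299 23.330679661280506
21.319236671413965 13.092801050818695 25.282872266909092
21.706781055532321 13.079055446086187 25.611485782405502
21.4317652985753 13.194358506403482 23.428765427217993
21.654017973745542 13.29069027391086 25.271691850476948
23.651980081775609 5.8329331689455266 23.486130447498375
23.885780239163559 5.8378427492231388 23.088007586008644
23.919726803666737 5.7118255758155243 23.488077173580972
23.969779773487264 5.8202445392289945 24.182568578733679
22.151839575488953 7.779747172825914 21.515057042913607
23.611099506090667 7.8053652852010806 20.578006163177072
23.742018159143928 6.5516083106456406 21.485544579178736
24.064331579092464 6.0422357653887779 25.394001812622779
24.200930857069075 7.5263472919800058 27.193232967301501
23.924775343093419 7.6871316691112561 27.179224256873749
24.20800932562916 7.6811476960698002 27.297349494219645
23.4728861527439 9.6844494738235234 20.257558962079198
24.223125458414525 9.516434444714978 27.903100356980563
21.6994074785656 11.464412414043693 21.486070148056296
23.406106423949179 11.472984274805134 20.641356813650997
22.036595616179987 11.349608806917255 27.066643273991172
24.153104964499722 11.294589999322945 27.796996593162397
23.430770095738492 12.630839077550728 21.385180487543092
23.474213466619382 13.14101575933581 21.943991851643229
24.025798951729691 12.79619082862331 27.048246906374899
23.99883415734006 13.017541928436183 26.846844249682963
23.610471188125626 13.90208048706871 23.3305731477192
23.809598420765646 13.969452022380219 25.204905817780713
25.921413238426382 5.8136208846287971 23.372337240133703
25.928304876333257 5.7818347230233691 23.467478306941512
25.94218611744941 5.8070056255012403 23.682853172491082
25.678722073276536 7.7791163243006629 20.629352382980532
25.767054912502111 6.7420071174722054 21.413268282791478
26.057319990826294 6.0452413050395428 25.413606582870305
26.180409971677811 7.477366340328679 27.247809112572732
26.187687481779648 7.6337844104883317 27.357347469200931
25.58607019208079 9.639498462280109 20.218625701844047
26.225116625396147 9.461969807385298 28.018859087996312
25.572478619504452 11.406155948989102 20.551599818115687
26.208440984532832 11.24566181678345 27.995135996903397
25.629344487247806 12.549003457078799 21.280639871303023
25.679734447709286 13.064379670897988 21.804783009017999
25.096335113092035 12.993522431008525 27.050822748197238
26.140859876371223 12.979990404871863 27.188997278869305
25.823573312608737 13.908062943929586 23.257990165750901
25.991188454697838 14.11010563632529 25.172991811075381
26.131810286703931 13.115171368133705 27.066004909183007
25.988898334766709 5.8109767379592974 23.465777730294466
26.919839737714984 7.7290950843923127 21.348661711336526
27.880376161669865 7.6723823662566915 22.518324154448777
27.938388424834486 7.1147477532356405 23.409651624327054
28.056002715305624 7.1928600993661682 25.392593087811168
26.452564138832837 7.6277214261958548 27.247835968421505
28.091095739176147 7.6052258985016898 25.968473722880571
27.723631806653884 9.5335930172021062 21.277061352361486
27.79567321133387 9.5292220590936072 21.340765955477728
28.176059819158713 9.3056161077134956 27.227644136793618
28.179968723147581 9.4235157339761368 27.275890744762783
27.260369651781744 11.310918866802604 21.243803044468077
27.834979368576967 11.278446305562698 21.622313869961147
28.210975973643411 11.214637888551479 27.348670087654547
27.996090174819155 12.951946117218156 23.147826834134655
26.526777310650004 12.972935895751657 27.073739872935764
28.210217820910401 11.674475739494724 27.147628717629949
28.182227059326522 12.95016393685987 26.02057340312389
28.004509761047661 13.009549860116291 23.237893114907138
28.146061162287786 13.360342096041252 25.193096649060966
28.404052231781034 7.6422920142842194 23.39159775497173
28.448732476447717 7.6072875911897846 25.382241765661867
29.213960944809806 9.4428567957380309 23.333365130868167
29.407836186992576 9.4166339953763547 25.331089350899646
28.243645407541571 9.422670236453385 27.225475905385785
29.181877049790931 11.208176276327656 23.280281736913505
29.54953767554364 11.198044520409987 25.275964201505023
28.445583398773422 11.211946608225571 27.170089195772032
28.077478999975096 12.949285697337116 23.238643194121838
28.644836978816361 12.942739055587818 25.209761320145095
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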