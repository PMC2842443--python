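# vtk DataFile Version 3.0
tractsurf surface
ASCII
DATASET POLYDATA
POINTS 98 double
21.564634835545455 7.9697285991445028 24.588110627951075
22.23473930372997 7.9835328140752191 23.305562233563776
22.221142051911468 7.1656340441015463 24.535292586915372
22.237558216426482 7.4272720993343775 26.53210044454995
21.7283687631184 7.9850372373041925 26.564033085294017
22.259076020829074 8.0066172554000961 27.288570439697086
22.139124297931978 9.9474983298603465 22.810210278516465
22.285103913269399 9.9516496818020812 22.689000194948822
22.270388827905926 9.4192684960960253 22.757205030219069
20.740884718979899 9.9157056369646437 24.750863636441444
20.648814586947882 9.9400809295901862 26.699690589553484
22.341336187130974 10.0208055534951 28.671948374306478
22.327495983123686 10.048749331862991 28.67365761345172
22.34264589810277 10.049668412096862 28.684364298722155
22.317518042598568 10.763609824423764 22.910851040653771
20.808515876640836 11.87316840007284 24.954736522648194
22.365665405515152 11.914198704547561 23.251730254135456
20.577791342206339 11.916489949662941 26.87369546417743
22.453305805188219 12.095025261073488 28.810370166668648
22.384721285063911 10.857101550667487 28.738294854082461
22.419010306161752 13.941645084157056 25.196693225842598
22.509179927634701 13.944005424916828 25.099735584227666
22.229111511445417 14.024624967467703 27.08981849855542
22.571491190295809 14.073142554906351 27.454645442260048
22.516148345682396 14.020386111762967 25.205051989539736
22.579552465271632 14.299118362563481 27.114606721961405
23.963129822974281 6.0263398239453325 24.486279793947801
24.228656587509366 6.0306188095959312 24.090910484779954
24.226398773855006 5.9057768628650269 24.482706425768423
24.235170083092449 6.0333202542669842 25.214493626168402
22.750983313330792 7.9959360181383357 22.621273698415337
24.263177161330272 8.0286377888866021 21.796814726139726
24.235329424969688 6.7411911575721115 22.546620379332733
24.245902449281889 6.2888235287404868 26.492487599577771
24.307328549362499 7.9196004689595938 28.561082146599368
24.032951380254698 8.0795469584129975 28.567037375399899
24.314414369851157 8.0912425971488524 28.689931907370688
24.323882558455686 10.013668806508077 21.739431366282737
24.416934589328996 10.1660979731403 29.553942940546943
22.71999830428171 11.928050053418778 23.053875194010217
24.408282681355765 12.0030655843006 22.367277050574369
22.49124168141811 12.098093879708216 28.829422538326323
24.550543752824833 12.25927517263427 29.634708492759941
24.49391339369409 13.391762745418161 23.252659574583916
24.547833631160767 14.048116804693011 23.866529965403135
24.683512494489392 14.069020300418279 28.993860796256623
24.702337415712634 14.332998270785561 28.804893315182913
24.662330113954319 15.112313361363219 25.316238250225723
24.748679065632938 15.389244897499978 27.203656328902365
26.274829347671929 6.0762198134950385 24.461123392961476
26.273942932087543 6.0448528913109838 24.551468319583357
26.277031852105448 6.0782499935773524 24.772910270229673
26.319881684528124 8.0811594866659284 22.017884246359294
26.291378802862823 7.0016941152685455 22.639453634146363
26.293997401566877 6.3795324471439816 26.55166347319626
26.366425149949311 7.9935215840252605 28.617133128158965
26.375166990324548 8.1704564393169896 28.750330563093957
26.389429548576825 10.094363019262371 21.896854520535349
26.49745582894565 10.271812944621399 29.666822288985106
26.482421106482281 12.124518018929622 22.473451434433205
26.652358688592322 12.396473355389858 29.840062924832729
26.575600698116769 13.54193349227875 23.326965616869376
26.632197237715634 14.217991053710362 23.891276370471477
25.783926934145505 14.431834696578301 29.03140633947114
26.82397127763225 14.517114488584449 29.175058913744127
26.765959893247881 15.402556097952443 25.372872619873331
26.877406880442486 15.820184381163893 27.253563527858482
26.836371351622446 14.681770902486861 29.061934304888837
26.337444168771896 6.0784358280152375 24.556453289775977
27.514574515317236 8.1289695068005781 22.802095274699074
28.409397658490047 8.1827917517368469 23.988948251019234
28.38866122891443 7.5988045529476285 24.769969308015025
28.407784735822556 7.7572811808069044 26.736798672542548
26.660657875481345 8.1805292481496608 28.640135017204866
28.437438359971178 8.2403577902877387 27.372673837159574
28.420322359055685 10.218695944424931 23.071812528955469
28.487722558981211 10.224078481362341 23.137431856411585
28.568694162162522 10.229430325749508 28.862408905487843
28.578733578240421 10.368303893886708 28.925271677106846
28.067605036954063 12.253967153156761 23.272110364375465
28.603954465532688 12.306484381233533 23.671025513205016
28.750642215309007 12.504940128728204 29.210856124693422
28.790435317032166 14.471301674485137 25.32339092169147
27.220181848989093 14.539428343413848 29.069577049175194
28.798508177914872 13.062345968507726 29.064052553773521
28.911744721519835 14.611221798250751 28.083911288401481
28.799162757648805 14.548804182383767 25.413869461263001
28.920238980575409 15.090642692443955 27.310702774922134
28.886540925051978 8.2194498649391559 24.852993116473414
28.832150619634149 8.250168720308837 26.798330184304021
29.793770821021649 10.355032925950619 25.121308684419873
29.911843979392621 10.40938625660042 27.051088223093195
28.64696644384723 10.37120339082397 28.876119779772768
29.852131771457376 12.460368348167314 25.328044037975634
30.162027735559207 12.54491685156553 27.244101548697241
28.997125113459308 12.515707912006624 29.04030498715521
28.86632965073483 14.482169403818482 25.41387908157045
29.380374298322071 14.612330526301122 27.317850862856947
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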