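subject_id,group,icv_mm3,mmse,path
con000,CON,1490862.0166593401,28.699139874862748,data/cohort/con000
con001,CON,1466780.9562319848,28.868638725049358,data/cohort/con001
con002,CON,1476228.7874215608,28.14088898044742,data/cohort/con002
con003,CON,1401717.5639457626,28.3602551599054,data/cohort/con003
con004,CON,1362550.797134239,29.181732204613706,data/cohort/con004
con005,CON,1562903.6846825033,27.564738470555845,data/cohort/con005
con006,CON,1449386.7567756928,28.818136933711248,data/cohort/con006
con007,CON,1442669.119237181,30.0,data/cohort/con007
con008,CON,1463339.263237257,30.0,data/cohort/con008
con009,CON,1296873.1675165964,29.285004678684658,data/cohort/con009
con010,CON,1454622.2589312806,29.590409680214755,data/cohort/con010
con011,CON,1392375.5827000355,27.196697215280242,data/cohort/con011
con012,CON,1354361.2596642997,29.430806443409622,data/cohort/con012
con013,CON,1174561.3001179919,28.519737412984547,data/cohort/con013
con014,CON,1397948.9742118248,26.94026306896276,data/cohort/con014
con015,CON,1357333.6156822906,28.0672737954751,data/cohort/con015
con016,CON,1421082.175984543,29.11643696312514,data/cohort/con016
con017,CON,1242306.3924815743,27.876229178525584,data/cohort/con017
con018,CON,1413487.0369501393,27.468986624975976,data/cohort/con018
ad019,AD,1556639.4955139777,24.111125097905738,data/cohort/ad019
ad020,AD,1484140.445784995,18.652518626899415,data/cohort/ad020
ad021,AD,1322270.195602981,20.411101263034418,data/cohort/ad021
ad022,AD,1294545.7772508939,19.590562036240943,data/cohort/ad022
ad023,AD,1406713.343522842,18.30966517386492,data/cohort/ad023
ad024,AD,1464813.4720147378,20.93618959295186,data/cohort/ad024
ad025,AD,1501838.231022685,20.28465069663065,data/cohort/ad025
ad026,AD,1515402.0954436993,20.782183426913633,data/cohort/ad026
ad027,AD,1322536.401431118,21.028699245534135,data/cohort/ad027
ad028,AD,1175493.9958100289,22.231029368094426,data/cohort/ad028
ad029,AD,1151520.4097028445,22.8045700491927,data/cohort/ad029
ad030,AD,1443266.2035441517,25.606799627620546,data/cohort/ad030
ad031,AD,1426210.8724287674,21.223977727029755,data/cohort/ad031
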