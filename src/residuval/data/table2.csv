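no,analyte,category,ilis_group,rsdr_10,rsdr_25,rsdr_50,rsdR_10,rsdR_25,rsdR_50,recovery_10,recovery_25,recovery_50,loq,r_squared
1,Metribuzin DADK,transformation_product,4,20.4,6.9,2.2,28.2,11.1,3.1,50.2,82.6,97.3,10,0.9976
2,Atrazine desethyl,transformation_product,1,8.4,2.6,2.9,16.9,9.7,4.2,99.1,87.7,93.1,1,0.9983
3,"2,6-Dichlorobenzamid",transformation_product,2,1.6,2.5,2.8,4.9,4.3,3.7,108.1,115.4,107.7,5,0.9955
4,Atrazine,herbicide,1,4.7,12.6,4.5,7.4,13.3,5.8,99.9,100.7,95.0,1,0.9958
5,Clomazone,herbicide,1,2.7,2.5,4.6,4.7,7.9,5.9,80.6,80.1,79.1,0.5,0.9989
6,Chlorothalonil,fungicide,4,4.3,4.2,6.2,7.8,9.9,8.0,92.8,121.2,114.8,0.1,0.9972
7,Metribuzin DA,transformation_product,4,11.1,4.2,3.3,16.9,7.5,4.3,80.9,89.6,92.2,10,0.9906
8,Pirimicarb,insecticide_acaricide,5,5.4,2.5,5.3,20.9,13.8,7.3,77.6,84.3,81.6,5,0.9991
9,Metribuzin,herbicide,5,4.3,4.0,3.6,8.3,6.2,4.7,88.2,97.3,97.3,1,0.9988
10,Ametryn,herbicide,5,8.0,5.0,2.5,11.6,12.1,6.1,74.8,78.7,78.1,10,0.9988
11,Metalaxyl,fungicide,6,11.5,4.8,5.0,15.0,8.1,6.5,108.5,95.9,103.3,25,0.9975
12,Prosulfocarb,herbicide,6,18.6,5.7,7.8,24.6,9.5,10.1,84.3,95.3,103.0,0.25,0.998
13,S-metolachlor,herbicide,7,7.1,7.1,5.6,13.3,9.5,7.4,106.9,104.6,98.8,5,0.9958
14,Dicofol,insecticide_acaricide,7,14.1,13.1,11.8,27.5,20.3,15.4,65.2,74.8,78.5,1,0.9965
15,Trifloxystrobin CGA,transformation_product,8,5.6,9.7,5.8,8.9,13.2,7.5,73.8,86.0,77.0,5,0.9963
16,Triadimenol,fungicide,7,2.6,4.2,2.8,9.5,5.7,3.7,92.2,94.8,93.0,5,0.9993
17,alpha-Endosulfane,insecticide_acaricide,7,7.7,7.2,6.0,10.5,11.7,7.8,74.0,81.0,83.6,0.1,0.9976
18,Oxyfluorfen,herbicide,7,9.5,6.8,4.9,12.6,9.2,6.3,97.3,97.4,97.2,25,0.993
19,Fluazifop-p-butyl,herbicide,7,8.1,4.6,3.6,14.4,7.4,4.8,106.0,101.7,101.5,0.1,0.9997
20,Cyproconazole,fungicide,8,2.7,6.3,5.4,3.8,8.4,7.0,82.2,73.2,70.5,5,0.9987
21,beta-Endosulfane,insecticide_acaricide,7,10.4,6.5,7.1,18.4,10.9,9.2,92.3,91.9,92.9,10,0.9952
22,Carfentrazone-ethyl,herbicide,8,7.1,6.5,4.0,9.5,8.7,5.2,89.1,89.3,91.5,1,0.995
23,Trifloxystrobin,fungicide,8,6.0,6.3,5.3,7.7,8.2,6.8,88.9,81.6,79.4,5,0.9988
24,Benalaxyl,fungicide,8,9.7,6.3,6.1,13.1,8.5,7.8,109.2,83.1,82.2,5,0.9982
25,Fluopicolide,fungicide,9,11.6,5.1,5.9,15.7,7.2,7.6,112.3,106.9,104.4,10,0.9969
26,Endosulfane sulphate,transformation_product,9,8.9,9.0,8.9,35.1,27.8,12.2,97.0,97.0,98.8,0.1,0.9933
27,Tebuconazole,fungicide,9,12.2,10.2,7.5,16.4,13.5,9.7,108.9,111.2,111.0,0.5,0.9989
28,Epoxiconazole,fungicide,9,9.5,8.6,6.1,14.6,14.8,7.9,83.4,92.9,89.4,0.1,0.9961
29,Bifenthrin,insecticide_acaricide,9,20.8,15.3,9.3,36.6,21.8,12.4,66.9,60.9,57.7,10,0.9962
30,Fenamidone,fungicide,9,7.5,9.1,5.0,14.8,15.3,6.6,93.6,86.9,84.2,5,0.9967
31,Benthiavalicarb-isopropyl,fungicide,9,7.7,7.9,5.6,13.9,13.7,7.3,89.3,93.0,89.5,1,0.9977
32,Fenamidone RPA,transformation_product,9,14.6,11.6,7.3,22.3,17.4,9.6,95.9,106.9,106.1,0.25,0.9972
33,Pyraclostrobin,fungicide,9,15.2,13.1,6.0,30.9,21.0,8.2,112.2,78.2,65.6,10,0.9985
34,Spirotetramat,insecticide_acaricide,9,12.3,11.9,5.0,16.5,17.3,6.5,80.6,82.5,79.6,5,0.9937
35,Boscalid,fungicide,10,9.7,8.3,6.0,13.6,11.3,7.8,86.7,88.7,83.6,0.1,0.9987
36,Deltamethrin,insecticide_acaricide,10,12.1,11.6,9.0,17.9,15.1,11.6,78.0,79.8,75.8,10,0.9995
37,Azoxystrobin,fungicide,10,8.0,4.8,3.9,13.1,7.0,5.1,101.8,100.7,99.1,0.5,0.9979
38,Dimethomorph,fungicide,10,6.5,7.1,4.7,10.0,9.8,6.0,87.7,90.4,87.7,0.1,0.9975
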