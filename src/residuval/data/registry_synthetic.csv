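name,category,ilis_group,si_ilis,expected_rt
Metribuzin DADK,transformation_product,4,True,7.10
Atrazine desethyl,transformation_product,3,True,6.85
"2,6-Dichlorobenzamid",transformation_product,2,True,6.20
Atrazine,herbicide,1,True,7.45
Clomazone,herbicide,1,False,7.70
Chlorothalonil,fungicide,4,False,7.90
Metribuzin DA,transformation_product,4,True,8.00
Pirimicarb,insecticide_acaricide,5,True,8.10
Metribuzin,herbicide,5,False,8.20
Ametryn,herbicide,5,False,8.30
Metalaxyl,fungicide,6,True,8.45
Prosulfocarb,herbicide,6,False,8.60
S-metolachlor,herbicide,7,True,8.80
Dicofol,insecticide_acaricide,7,False,8.95
Trifloxystrobin CGA,transformation_product,8,False,9.05
Triadimenol,fungicide,7,False,9.15
alpha-Endosulfane,insecticide_acaricide,7,False,9.30
Oxyfluorfen,herbicide,7,False,9.45
Fluazifop-p-butyl,herbicide,7,False,9.60
Cyproconazole,fungicide,8,True,9.75
beta-Endosulfane,insecticide_acaricide,7,False,9.95
Carfentrazone-ethyl,herbicide,8,False,10.10
Trifloxystrobin,fungicide,8,False,10.25
Benalaxyl,fungicide,8,False,10.40
Fluopicolide,fungicide,9,True,10.60
Endosulfane sulphate,transformation_product,9,False,10.80
Tebuconazole,fungicide,9,False,10.95
Epoxiconazole,fungicide,9,False,11.15
Bifenthrin,insecticide_acaricide,9,False,11.55
Fenamidone,fungicide,9,False,11.70
Benthiavalicarb-isopropyl,fungicide,9,False,11.85
Fenamidone RPA,transformation_product,9,False,12.00
Pyraclostrobin,fungicide,9,False,12.30
Spirotetramat,insecticide_acaricide,9,False,12.45
Boscalid,fungicide,10,False,12.90
Deltamethrin,insecticide_acaricide,10,False,13.60
Azoxystrobin,fungicide,10,True,13.30
Dimethomorph,fungicide,10,False,13.80
Atrazine-D5,internal_standard,1,False,7.44
"2,6-Dichlorobenzamide-D3",internal_standard,2,False,6.19
Atrazine-desethyl-D7,internal_standard,3,False,6.84
n-Methyl-metribuzin-D3,internal_standard,4,False,8.01
Pirimicarb-D6,internal_standard,5,False,8.09
Metalaxyl-D6,internal_standard,6,False,8.44
Metolachlor-D6,internal_standard,7,False,8.79
Cyproconazole-D3,internal_standard,8,False,9.74
Fluopicolide-D4,internal_standard,9,False,10.59
Azoxystrobin-D4,internal_standard,10,False,13.29
Triphenyl phosphate,syringe_standard,0,False,12.70
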