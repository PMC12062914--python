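# International Classification of Childhood Cancer, third edition (ICCC-3):
# 12 main diagnostic groups (Roman numerals, empty parent) and 47 subgroups
# (lower-case letter suffix, parent = main-group code). Group V
# (retinoblastoma) has no subgroups.
code,label,parent
I,"Leukaemias, myeloproliferative and myelodysplastic diseases",
Ia,Lymphoid leukaemias,I
Ib,Acute myeloid leukaemias,I
Ic,Chronic myeloproliferative diseases,I
Id,Myelodysplastic syndrome and other myeloproliferative diseases,I
Ie,Unspecified and other specified leukaemias,I
II,Lymphomas and reticuloendothelial neoplasms,
IIa,Hodgkin lymphomas,II
IIb,Non-Hodgkin lymphomas (except Burkitt lymphoma),II
IIc,Burkitt lymphoma,II
IId,Miscellaneous lymphoreticular neoplasms,II
IIe,Unspecified lymphomas,II
III,CNS and miscellaneous intracranial and intraspinal neoplasms,
IIIa,Ependymomas and choroid plexus tumour,III
IIIb,Astrocytomas,III
IIIc,Intracranial and intraspinal embryonal tumours,III
IIId,Other gliomas,III
IIIe,Other specified intracranial and intraspinal neoplasms,III
IIIf,Unspecified intracranial and intraspinal neoplasms,III
IV,Neuroblastoma and other peripheral nervous cell tumours,
IVa,Neuroblastoma and ganglioneuroblastoma,IV
IVb,Other peripheral nervous cell tumours,IV
V,Retinoblastoma,
VI,Renal tumours,
VIa,Nephroblastoma and other nonepithelial renal tumours,VI
VIb,Renal carcinomas,VI
VIc,Unspecified malignant renal tumours,VI
VII,Hepatic tumours,
VIIa,Hepatoblastoma,VII
VIIb,Hepatic carcinomas,VII
VIIc,Unspecified malignant hepatic tumours,VII
VIII,Malignant bone tumours,
VIIIa,Osteosarcomas,VIII
VIIIb,Chondrosarcomas,VIII
VIIIc,Ewing tumour and related sarcomas of bone,VIII
VIIId,Other specified malignant bone tumours,VIII
VIIIe,Unspecified malignant bone tumours,VIII
IX,Soft tissue and other extraosseous sarcomas,
IXa,Rhabdomyosarcomas,IX
IXb,"Fibrosarcomas, peripheral nerve sheath tumours and other fibrous neoplasms",IX
IXc,Kaposi sarcoma,IX
IXd,Other specified soft tissue sarcomas,IX
IXe,Unspecified soft tissue sarcomas,IX
X,"Germ cell tumours, trophoblastic tumours and neoplasms of gonads",
Xa,Intracranial and intraspinal germ cell tumours,X
Xb,Malignant extracranial and extragonadal germ cell tumours,X
Xc,Malignant gonadal germ cell tumours,X
Xd,Gonadal carcinomas,X
Xe,Other and unspecified malignant gonadal tumours,X
XI,Other malignant epithelial neoplasms and malignant melanomas,
XIa,Adrenocortical carcinomas,XI
XIb,Thyroid carcinomas,XI
XIc,Nasopharyngeal carcinomas,XI
XId,Malignant melanomas,XI
XIe,Skin carcinomas,XI
XIf,Other and unspecified carcinomas,XI
XII,Other and unspecified malignant neoplasms,
XIIa,Other specified malignant tumours,XII
XIIb,Other unspecified malignant tumours,XII
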