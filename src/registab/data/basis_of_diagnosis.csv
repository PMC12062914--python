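# IARC/IACR basis-of-diagnosis codes and their role for the data-quality
# indicators: role "microscopic" counts toward MV%, role "dco" toward DCO%.
# Registries using a national variant can substitute this table.
code,role,label
0,dco,Death certificate only
1,clinical,Clinical only
2,clinical,"Clinical investigation (X-ray, endoscopy, imaging)"
3,clinical,Exploratory surgery / autopsy without tissue diagnosis
4,clinical,Specific biochemical and/or immunological tumour markers
5,microscopic,Cytology or haematology
6,microscopic,Histology of a metastasis
7,microscopic,Histology of a primary tumour
8,microscopic,Autopsy with concurrent or previous histology
9,unknown,Unknown
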