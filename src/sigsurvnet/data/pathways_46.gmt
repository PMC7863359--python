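MAPK	synthetic placeholder membership	SG00_00	SG00_01	SG00_02	SG00_03	SG00_04	SG00_05	SG00_06	SG00_07	SG00_08	SG00_09	SG00_10	SG00_11	SG00_12	SG00_13	SG00_14
FoxO	synthetic placeholder membership	SG00_13	SG00_14	SG01_00	SG01_01	SG01_02	SG01_03	SG01_04	SG01_05	SG01_06	SG01_07	SG01_08	SG01_09	SG01_10	SG01_11	SG01_12
TGF-beta	synthetic placeholder membership	SG01_11	SG01_12	SG02_00	SG02_01	SG02_02	SG02_03	SG02_04	SG02_05	SG02_06	SG02_07	SG02_08	SG02_09	SG02_10	SG02_11	SG02_12
T cell receptor	synthetic placeholder membership	SG02_11	SG02_12	SG03_00	SG03_01	SG03_02	SG03_03	SG03_04	SG03_05	SG03_06	SG03_07	SG03_08	SG03_09	SG03_10	SG03_11	SG03_12
Adipocytokine	synthetic placeholder membership	SG03_11	SG03_12	SG04_00	SG04_01	SG04_02	SG04_03	SG04_04	SG04_05	SG04_06	SG04_07	SG04_08	SG04_09	SG04_10	SG04_11	SG04_12
ErbB	synthetic placeholder membership	SG04_11	SG04_12	SG05_00	SG05_01	SG05_02	SG05_03	SG05_04	SG05_05	SG05_06	SG05_07	SG05_08	SG05_09	SG05_10	SG05_11	SG05_12
Sphingolipid	synthetic placeholder membership	SG05_11	SG05_12	SG06_00	SG06_01	SG06_02	SG06_03	SG06_04	SG06_05	SG06_06	SG06_07	SG06_08	SG06_09	SG06_10	SG06_11	SG06_12
VEGF	synthetic placeholder membership	SG06_11	SG06_12	SG07_00	SG07_01	SG07_02	SG07_03	SG07_04	SG07_05	SG07_06	SG07_07	SG07_08	SG07_09	SG07_10	SG07_11	SG07_12
B cell receptor	synthetic placeholder membership	SG07_11	SG07_12	SG08_00	SG08_01	SG08_02	SG08_03	SG08_04	SG08_05	SG08_06	SG08_07	SG08_08	SG08_09	SG08_10	SG08_11	SG08_12
Oxytocin	synthetic placeholder membership	SG08_11	SG08_12	SG09_00	SG09_01	SG09_02	SG09_03	SG09_04	SG09_05	SG09_06	SG09_07	SG09_08	SG09_09	SG09_10	SG09_11	SG09_12
Ras	synthetic placeholder membership	SG09_11	SG09_12	SG10_00	SG10_01	SG10_02	SG10_03	SG10_04	SG10_05	SG10_06	SG10_07	SG10_08	SG10_09	SG10_10	SG10_11	SG10_12
Phospholipase D	synthetic placeholder membership	SG10_11	SG10_12	SG11_00	SG11_01	SG11_02	SG11_03	SG11_04	SG11_05	SG11_06	SG11_07	SG11_08	SG11_09	SG11_10	SG11_11	SG11_12
Apelin	synthetic placeholder membership	SG11_11	SG11_12	SG12_00	SG12_01	SG12_02	SG12_03	SG12_04	SG12_05	SG12_06	SG12_07	SG12_08	SG12_09	SG12_10	SG12_11	SG12_12
Fc epsilon RI	synthetic placeholder membership	SG12_11	SG12_12	SG13_00	SG13_01	SG13_02	SG13_03	SG13_04	SG13_05	SG13_06	SG13_07	SG13_08	SG13_09	SG13_10	SG13_11	SG13_12
Glucagon	synthetic placeholder membership	SG13_11	SG13_12	SG14_00	SG14_01	SG14_02	SG14_03	SG14_04	SG14_05	SG14_06	SG14_07	SG14_08	SG14_09	SG14_10	SG14_11	SG14_12
Rap1	synthetic placeholder membership	SG14_11	SG14_12	SG15_00	SG15_01	SG15_02	SG15_03	SG15_04	SG15_05	SG15_06	SG15_07	SG15_08	SG15_09	SG15_10	SG15_11	SG15_12
p53	synthetic placeholder membership	SG15_11	SG15_12	SG16_00	SG16_01	SG16_02	SG16_03	SG16_04	SG16_05	SG16_06	SG16_07	SG16_08	SG16_09	SG16_10	SG16_11	SG16_12
Hippo	synthetic placeholder membership	SG16_11	SG16_12	SG17_00	SG17_01	SG17_02	SG17_03	SG17_04	SG17_05	SG17_06	SG17_07	SG17_08	SG17_09	SG17_10	SG17_11	SG17_12
TNF	synthetic placeholder membership	SG17_11	SG17_12	SG18_00	SG18_01	SG18_02	SG18_03	SG18_04	SG18_05	SG18_06	SG18_07	SG18_08	SG18_09	SG18_10	SG18_11	SG18_12
Relaxin	synthetic placeholder membership	SG18_11	SG18_12	SG19_00	SG19_01	SG19_02	SG19_03	SG19_04	SG19_05	SG19_06	SG19_07	SG19_08	SG19_09	SG19_10	SG19_11	SG19_12
Calcium	synthetic placeholder membership	SG19_11	SG19_12	SG20_00	SG20_01	SG20_02	SG20_03	SG20_04	SG20_05	SG20_06	SG20_07	SG20_08	SG20_09	SG20_10	SG20_11	SG20_12
mTOR	synthetic placeholder membership	SG20_11	SG20_12	SG21_00	SG21_01	SG21_02	SG21_03	SG21_04	SG21_05	SG21_06	SG21_07	SG21_08	SG21_09	SG21_10	SG21_11	SG21_12
Toll-like receptor	synthetic placeholder membership	SG21_11	SG21_12	SG22_00	SG22_01	SG22_02	SG22_03	SG22_04	SG22_05	SG22_06	SG22_07	SG22_08	SG22_09	SG22_10	SG22_11	SG22_12
Neurotrophin	synthetic placeholder membership	SG22_11	SG22_12	SG23_00	SG23_01	SG23_02	SG23_03	SG23_04	SG23_05	SG23_06	SG23_07	SG23_08	SG23_09	SG23_10	SG23_11	SG23_12
AGE-RAGE	synthetic placeholder membership	SG23_11	SG23_12	SG24_00	SG24_01	SG24_02	SG24_03	SG24_04	SG24_05	SG24_06	SG24_07	SG24_08	SG24_09	SG24_10	SG24_11	SG24_12
cGMP-PKG	synthetic placeholder membership	SG24_11	SG24_12	SG25_00	SG25_01	SG25_02	SG25_03	SG25_04	SG25_05	SG25_06	SG25_07	SG25_08	SG25_09	SG25_10	SG25_11	SG25_12
PI3K-Akt	synthetic placeholder membership	SG25_11	SG25_12	SG26_00	SG26_01	SG26_02	SG26_03	SG26_04	SG26_05	SG26_06	SG26_07	SG26_08	SG26_09	SG26_10	SG26_11	SG26_12
NOD-like receptor	synthetic placeholder membership	SG26_11	SG26_12	SG27_00	SG27_01	SG27_02	SG27_03	SG27_04	SG27_05	SG27_06	SG27_07	SG27_08	SG27_09	SG27_10	SG27_11	SG27_12
Insulin	synthetic placeholder membership	SG27_11	SG27_12	SG28_00	SG28_01	SG28_02	SG28_03	SG28_04	SG28_05	SG28_06	SG28_07	SG28_08	SG28_09	SG28_10	SG28_11	SG28_12
Cell cycle	synthetic placeholder membership	SG28_11	SG28_12	SG29_00	SG29_01	SG29_02	SG29_03	SG29_04	SG29_05	SG29_06	SG29_07	SG29_08	SG29_09	SG29_10	SG29_11	SG29_12
cAMP	synthetic placeholder membership	SG29_11	SG29_12	SG30_00	SG30_01	SG30_02	SG30_03	SG30_04	SG30_05	SG30_06	SG30_07	SG30_08	SG30_09	SG30_10	SG30_11	SG30_12
AMPK	synthetic placeholder membership	SG30_11	SG30_12	SG31_00	SG31_01	SG31_02	SG31_03	SG31_04	SG31_05	SG31_06	SG31_07	SG31_08	SG31_09	SG31_10	SG31_11	SG31_12
RIG-I-like receptor	synthetic placeholder membership	SG31_11	SG31_12	SG32_00	SG32_01	SG32_02	SG32_03	SG32_04	SG32_05	SG32_06	SG32_07	SG32_08	SG32_09	SG32_10	SG32_11	SG32_12
GnRH	synthetic placeholder membership	SG32_11	SG32_12	SG33_00	SG33_01	SG33_02	SG33_03	SG33_04	SG33_05	SG33_06	SG33_07	SG33_08	SG33_09	SG33_10	SG33_11	SG33_12
Chemokine	synthetic placeholder membership	SG33_11	SG33_12	SG34_00	SG34_01	SG34_02	SG34_03	SG34_04	SG34_05	SG34_06	SG34_07	SG34_08	SG34_09	SG34_10	SG34_11	SG34_12
Wnt	synthetic placeholder membership	SG34_11	SG34_12	SG35_00	SG35_01	SG35_02	SG35_03	SG35_04	SG35_05	SG35_06	SG35_07	SG35_08	SG35_09	SG35_10	SG35_11	SG35_12
C-type lectin receptor	synthetic placeholder membership	SG35_11	SG35_12	SG36_00	SG36_01	SG36_02	SG36_03	SG36_04	SG36_05	SG36_06	SG36_07	SG36_08	SG36_09	SG36_10	SG36_11	SG36_12
Estrogen	synthetic placeholder membership	SG36_11	SG36_12	SG37_00	SG37_01	SG37_02	SG37_03	SG37_04	SG37_05	SG37_06	SG37_07	SG37_08	SG37_09	SG37_10	SG37_11	SG37_12
NF-kappa B	synthetic placeholder membership	SG37_11	SG37_12	SG38_00	SG38_01	SG38_02	SG38_03	SG38_04	SG38_05	SG38_06	SG38_07	SG38_08	SG38_09	SG38_10	SG38_11	SG38_12
Notch	synthetic placeholder membership	SG38_11	SG38_12	SG39_00	SG39_01	SG39_02	SG39_03	SG39_04	SG39_05	SG39_06	SG39_07	SG39_08	SG39_09	SG39_10	SG39_11	SG39_12
JAK-STAT	synthetic placeholder membership	SG39_11	SG39_12	SG40_00	SG40_01	SG40_02	SG40_03	SG40_04	SG40_05	SG40_06	SG40_07	SG40_08	SG40_09	SG40_10	SG40_11	SG40_12
Prolactin	synthetic placeholder membership	SG40_11	SG40_12	SG41_00	SG41_01	SG41_02	SG41_03	SG41_04	SG41_05	SG41_06	SG41_07	SG41_08	SG41_09	SG41_10	SG41_11	SG41_12
HIF-1	synthetic placeholder membership	SG41_11	SG41_12	SG42_00	SG42_01	SG42_02	SG42_03	SG42_04	SG42_05	SG42_06	SG42_07	SG42_08	SG42_09	SG42_10	SG42_11	SG42_12
Hedgehog	synthetic placeholder membership	SG42_11	SG42_12	SG43_00	SG43_01	SG43_02	SG43_03	SG43_04	SG43_05	SG43_06	SG43_07	SG43_08	SG43_09	SG43_10	SG43_11	SG43_12
IL-17	synthetic placeholder membership	SG43_11	SG43_12	SG44_00	SG44_01	SG44_02	SG44_03	SG44_04	SG44_05	SG44_06	SG44_07	SG44_08	SG44_09	SG44_10	SG44_11	SG44_12
Thyroid hormone	synthetic placeholder membership	SG44_11	SG44_12	SG45_00	SG45_01	SG45_02	SG45_03	SG45_04	SG45_05	SG45_06	SG45_07	SG45_08	SG45_09	SG45_10	SG45_11	SG45_12
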