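name	formula	monoisotopic_mass
glycine	C2H5NO2	75.03203
alanine	C3H7NO2	89.04768
serine	C3H7NO3	105.04259
proline	C5H9NO2	115.06333
valine	C5H11NO2	117.07898
threonine	C4H9NO3	119.05824
cysteine	C3H7NO2S	121.01975
leucine	C6H13NO2	131.09463
isoleucine	C6H13NO2	131.09463
asparagine	C4H8N2O3	132.05349
aspartate	C4H7NO4	133.03751
glutamine	C5H10N2O3	146.06914
lysine	C6H14N2O2	146.10553
glutamate	C5H9NO4	147.05316
methionine	C5H11NO2S	149.05105
histidine	C6H9N3O2	155.06948
phenylalanine	C9H11NO2	165.07898
arginine	C6H14N4O2	174.11168
tyrosine	C9H11NO3	181.07389
tryptophan	C11H12N2O2	204.08988
citrulline	C6H13N3O3	175.09569
ornithine	C5H12N2O2	132.08988
sarcosine	C3H7NO2	89.04768
dimethylglycine	C4H9NO2	103.06333
taurine	C2H7NO3S	125.01466
betaine	C5H11NO2	117.07898
creatine	C4H9N3O2	131.06948
creatinine	C4H7N3O	113.05891
carnitine	C7H15NO3	161.10519
acetylcarnitine	C9H17NO4	203.11576
choline	C5H13NO	103.09971
glucose	C6H12O6	180.06339
fructose	C6H12O6	180.06339
galactose	C6H12O6	180.06339
mannose	C6H12O6	180.06339
ribose	C5H10O5	150.05282
xylose	C5H10O5	150.05282
sucrose	C12H22O11	342.11621
cellobiose	C12H22O11	342.11621
lactose	C12H22O11	342.11621
trehalose	C12H22O11	342.11621
maltose	C12H22O11	342.11621
myo-inositol	C6H12O6	180.06339
glycerol	C3H8O3	92.04734
glucose-6-phosphate	C6H13O9P	260.02972
glyceraldehyde-3-phosphate	C3H7O6P	169.99802
lactate	C3H6O3	90.03169
pyruvate	C3H4O3	88.01604
citrate	C6H8O7	192.02700
succinate	C4H6O4	118.02661
fumarate	C4H4O4	116.01096
malate	C4H6O5	134.02152
oxaloacetate	C4H4O5	132.00587
alpha-ketoglutarate	C5H6O5	146.02152
urea	CH4N2O	60.03236
uric acid	C5H4N4O3	168.02834
hypoxanthine	C5H4N4O	136.03851
xanthine	C5H4N4O2	152.03343
inosine	C10H12N4O5	268.08077
adenosine	C10H13N5O4	267.09675
hippurate	C9H9NO3	179.05824
indoxyl sulfate	C8H7NO4S	213.00958
p-cresol sulfate	C7H8O4S	188.01433
niacinamide	C6H6N2O	122.04801
pantothenate	C9H17NO5	219.11067
glutathione	C10H17N3O6S	307.08381
sphingosine	C18H37NO2	299.28243
uracil	C4H4N2O2	112.02728
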