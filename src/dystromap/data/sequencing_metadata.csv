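cohort,sample,reads_site_a,reads_site_b,spots_under_tissue
HC,1,,179385012,1596
HC,2,69722279,,1286
HC,3,,72827267,1911
HC,4,,163077843,3390
DYS,1,57881174,15777089,1646
DYS,2,34898373,22415086,805
DYS,3,28357053,,1136
DYS,4,70365978,64408453,1718
DYS,5,,82090390,856
DYS,6,60427341,11199628,1596
DYS,7,66184467,13392381,1398
DYS,8,70840919,42515602,2099
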