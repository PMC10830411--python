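raw_term,life_cycle,growth_form
annual,annual,none
annuals,annual,none
annual herb,annual,herbaceous
winter annual,annual,herbaceous
summer annual,annual,herbaceous
therophyte,annual,herbaceous
perennial,perennial,none
perennials,perennial,none
perennial herb,perennial,herbaceous
perennial forb,perennial,herbaceous
10 years,perennial,none
herb,none,herbaceous
forb,none,herbaceous
forb/herb,none,herbaceous
graminoid,none,herbaceous
grass,none,herbaceous
terrestrial herb,none,herbaceous
tree,perennial,woody
shrub,perennial,woody
subshrub,perennial,woody
tree/shrub,perennial,woody
woody,perennial,woody
woody perennial,perennial,woody
liana,perennial,woody
shrub/herb,none,conflict
tree/terrestrial herb,none,conflict
biennial,none,herbaceous
aquatic,none,none
epiphyte,none,none
terrestrial_trailing_plant,none,none
no,none,none
2.4,none,none
b h,none,none
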