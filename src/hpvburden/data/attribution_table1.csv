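# HPV type-attribution fractions by cancer site (and sex where the source
# distinguishes it), expressed as percentages of cancers at each site
# attributable to any HPV, to HPV 16/18, and to HPV 31/33/45/52/58.
# Source scale: CDC tissue-typing study estimates for 2008-2010.
site,sex,pct_any_hpv,pct_hpv_16_18,pct_hpv_31_33_45_52_58
cervix,,90.6,66.2,14.7
vagina,,75.0,55.1,18.3
vulva,,68.8,48.6,14.2
penis,,63.3,47.9,9.0
anus,female,92.5,79.5,10.8
anus,male,88.7,79.1,3.8
oropharynx,female,63.3,50.8,9.5
oropharynx,male,72.4,63.4,4.4
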