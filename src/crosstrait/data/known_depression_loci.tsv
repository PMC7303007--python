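gene	first_reported
NEGR1	Hyde et al. 2016 (self-reported MDD)
MAT2B	Hyde et al. 2016 (self-reported MDD)
ITIH3	Cross-Disorder Group of the PGC 2013
CACNA1C	Cross-Disorder Group of the PGC 2013
FHIT	Direk et al. 2017 (broad depression)
BAG5	Wray et al. 2018 (MDD)
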