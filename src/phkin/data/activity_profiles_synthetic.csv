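enzyme,ph,vmax
HXK,6.19,0.42
HXK,6.4,1.1
HXK,6.6,1.8
HXK,6.8,2.5
HXK,7.1,2.6
HXK,7.4,2.55
HXK,7.6,2.45
HXK,7.9,2.3
PGI,6.19,1.2
PGI,6.4,1.6
PGI,6.6,2.6
PGI,6.8,3.5
PGI,7.1,4.5
PGI,7.4,5.5
PGI,7.6,6.0
PGI,7.9,6.5
PFK,6.19,0.08
PFK,6.4,0.13
PFK,6.6,0.18
PFK,6.8,0.25
PFK,7.1,0.26
PFK,7.4,0.22
PFK,7.6,0.19
PFK,7.9,0.15
ALD,6.19,0.057
ALD,6.4,0.12
ALD,6.6,0.25
ALD,6.8,0.5
ALD,7.1,0.55
ALD,7.4,0.45
ALD,7.6,0.38
ALD,7.9,0.3
GAPDHF,6.19,0.3
GAPDHF,6.4,0.34
GAPDHF,6.6,0.6
GAPDHF,6.8,1.0
GAPDHF,7.1,2.0
GAPDHF,7.4,3.2
GAPDHF,7.6,4.5
GAPDHF,7.9,6.5
GAPDHR,6.19,3.0
GAPDHR,6.4,4.2
GAPDHR,6.6,3.9
GAPDHR,6.8,3.0
GAPDHR,7.1,3.0
GAPDHR,7.4,2.4
GAPDHR,7.6,2.0
GAPDHR,7.9,1.7
PGM,6.19,1.24
PGM,6.4,3.1
PGM,6.6,5.0
PGM,6.8,7.0
PGM,7.1,7.5
PGM,7.4,7.8
PGM,7.6,7.6
PGM,7.9,7.2
ENO,6.19,0.3
ENO,6.4,0.45
ENO,6.6,0.75
ENO,6.8,1.0
ENO,7.1,1.3
ENO,7.4,1.6
ENO,7.6,1.8
ENO,7.9,2.0
PYK,6.19,5.03
PYK,6.4,5.3
PYK,6.6,5.7
PYK,6.8,6.0
PYK,7.1,6.1
PYK,7.4,6.0
PYK,7.6,5.9
PYK,7.9,5.76
PDC,6.19,0.5
PDC,6.4,0.65
PDC,6.6,0.85
PDC,6.8,1.0
PDC,7.1,0.95
PDC,7.4,0.8
PDC,7.6,0.7
PDC,7.9,0.55
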