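gene	mechanism	pattern_text
SPPL2A	pattern	LFT/SFLC/LF/FSLC|SLIH/FVL/LSAHG/IFGV
SPPL2B	pattern	LFT/SFLC/LF/FSLC|SLIH/FVL/LSAHG/IFGV
CTSD	pssm	
CTSV	pssm	
CTSL	pssm	
CTSK	pssm	
LGMN	pssm	
CTSO	pattern	x/x/FR/R|x/x/x/x
CTSS	pssm	
CTSF	pattern	x/x/FLVK/x|x/x/x/x
BACE1	pattern	EG/VIL/x/LF|x/AV/x/VF
CTSC	pattern	x/x/x(not R or K)/ES|x(not P)/x/x/x
CTSH	pattern	x/x/x/R|x/x/x/x
CTSB	pssm	
CPQ	pattern	x/x/x/x|F/x/x/x
PRCP	pattern	x/x/x/P|x/x/x/x
TPP1	pattern	x/x/GP/FMG|F/RL/x/P
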