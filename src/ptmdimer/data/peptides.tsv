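# Bundled H3(1-12) study peptides: label<TAB>annotation
P0M0 (ala)	ARTKQTARKSTG-NME
P0M0 (ace)	ACE-RTKQTARKSTG-NME
P1M2	ART[ph]K[me3]QTAR[me2]KSTG-NME
P2M4	ACE-R[me2]T[ph]K[me3]QTAR[me2]K[me3]S[ph]TG-NME
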