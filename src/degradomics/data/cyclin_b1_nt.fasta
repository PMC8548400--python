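>CCNB1_NT synthetic transcription of the human cyclin B1 N-terminal region (residues 1-88; disordered, degron R42-N50, 15 lysines)
MALRVTRNSKINAENKAKINMAGAKRVPTAPAATSKPGLRPRTALGDIGNKVSEQLQAKL
PLPKEAKPKATGKVIDKKLPKPLEKVPM
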