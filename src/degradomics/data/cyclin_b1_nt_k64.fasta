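>CCNB1_NT_K64 synthetic transcription of the K64-only Cyclin B1-NT construct (all Lys->Arg except K64; isopeptide anchor for ubiquitin conjugation)
MALRVTRNSRINAENRARINMAGARRVPTAPAATSRPGLRPRTALGDIGNRVSEQLQARL
PLPKEARPRATGRVIDRRLPRPLERVPM
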