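>UBIQUITIN human ubiquitin, 76 aa; C-terminus ...LRLRGG leaves GG/RGG/LRGG isopeptide remnants on substrate lysines
MQIFVKTLTGKTITLEVEPSDTIENVKAKIQDKEGIPPDQQRLIFAGKQLEDGRTLSDYN
IQKESTLHLVLRLRGG
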