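(Phacochoerus_africanus,((Sus_barbatus,(Sus_verrucosus,(Sus_cebifrons,Sus_celebensis)2.2)2.8)3.2,(Sumatra,((European_domestic,European_wild)0.01,((Southern_Chinese_wild,Southern_Chinese_domestic)0.01,(Tibetan_wild,(Northern_Chinese_wild,Northern_Chinese_domestic)0.01)0.2)0.6)1.0)2.0)3.5)11.0;
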