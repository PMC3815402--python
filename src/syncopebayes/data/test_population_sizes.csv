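population,n_cardiac,n_noncardiac
calgary,138,525
amsterdam,44,419
milan,37,652
rochester,424,3453
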