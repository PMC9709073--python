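level,soc,term,a,ror,ror_low,ror_high,prr,chi2,ic,ic025,ebgm,ebgm05,ror_sig,prr_sig,ic_sig,ebgm_sig,all_four,expected
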