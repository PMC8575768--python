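rrna	nm_sites	psi_sites
LSU	107	23
SSU	74	16
5.8S	2	2
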