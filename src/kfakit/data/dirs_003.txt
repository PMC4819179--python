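0.366421630107 -0.919338460033 0.143359634810
-0.912007356767 -0.324346586353 0.251081407364
0.184330591313 0.222746691741 0.957291044785
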