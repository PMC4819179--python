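-0.302311826664 0.951949014313 0.048996261161
0.827394238450 0.542994834771 0.143441219988
0.738916302596 -0.334805724828 0.584728846886
-0.445472299453 -0.468361944323 0.763014757085
-0.120953342870 0.455564065500 0.881947657786
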