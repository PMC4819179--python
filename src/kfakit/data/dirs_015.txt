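-0.219143354641 -0.975690714058 0.001954640065
-0.963648650755 0.266645520581 0.016776300289
-0.507917855327 0.860568684912 0.037960384460
-0.830656975852 -0.550753212189 0.081730580155
0.872415087158 0.146584171960 0.466267086796
0.524694832260 0.702184562217 0.481281802673
0.162392342049 -0.854554003667 0.493321580777
-0.660918318942 0.514456364683 0.546371324764
-0.820104011852 -0.121407043437 0.559186676834
0.682737650197 -0.458284901190 0.569073150258
-0.443495296574 -0.636611832164 0.630901971043
-0.086570840220 0.767130548048 0.635622696161
0.357098924523 0.227688956523 0.905890775525
0.108433578890 -0.364099173819 0.925026459402
-0.310973158335 0.121908557106 0.942567768651
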