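-0.940999783294 -0.336153372116 0.038991258717
-0.790463956586 0.609150779245 0.064047337837
0.086628760107 0.992975882603 0.080587557917
0.265835624366 -0.766671946110 0.584418983149
0.790880224430 -0.087581284706 0.605671519204
-0.553254824548 -0.548033947744 0.627349895380
0.371537815157 0.648090506677 0.664784436538
-0.552143026904 0.404068642843 0.729291854961
0.027991319232 -0.052881609298 0.998208405818
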