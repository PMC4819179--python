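0.001538947297 -0.998081611138 0.061892884484
0.665138182124 0.743606194430 0.068125078249
0.539357269954 -0.829723801898 0.143708551978
0.981872275852 0.097904089926 0.162301026148
0.869865082323 -0.460225157532 0.177559969954
-0.889320069464 -0.399938731730 0.221717894882
-0.949606081339 0.177120655945 0.258605033828
-0.308022093655 0.894393907629 0.324317634142
-0.389087574918 -0.857832679213 0.335758772810
0.273092845065 0.899606942183 0.340775068852
-0.714088029864 0.606743039720 0.349200757955
0.773325343959 0.441712990734 0.454815947618
0.164528727832 -0.842716302696 0.512600751939
0.806112714275 -0.125443049879 0.578313352017
-0.604186730331 -0.506933301940 0.614798359038
0.545124577525 -0.545892660295 0.636270695864
-0.759373477110 -0.028897537555 0.650012964936
0.376151414706 0.589057783346 0.715206991782
-0.117788506204 0.688376813472 0.715725667054
-0.510324599493 0.386072065752 0.768451145616
-0.140561231034 -0.595334914685 0.791087150500
0.501023738528 0.121939437567 0.856799852356
0.218334458990 -0.280914937824 0.934567740576
-0.328641287139 -0.125906804524 0.936024775827
0.001866122398 0.243591389621 0.969876153171
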