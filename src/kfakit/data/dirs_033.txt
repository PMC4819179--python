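0.906609865608 0.421940379382 0.004986765385
-0.228867203049 -0.972335984699 0.046717622235
0.641326523081 0.760902044367 0.098632498051
0.990909007002 -0.040253408138 0.128370568963
-0.886273135500 0.431357834604 0.168672308982
-0.602234602514 0.769492715228 0.212589850994
-0.199590447909 0.956082389397 0.214639506586
0.179487066769 -0.959946206976 0.215145700805
0.583450164582 -0.782565056199 0.217204600009
0.858973063995 -0.440723083810 0.260630847614
-0.952080885373 -0.048261788982 0.302014548378
-0.532543556137 -0.780686003813 0.326996520269
0.267695272047 0.883820968779 0.383666178429
-0.786084947968 -0.456727964018 0.416497324676
0.861580184028 0.284623672380 0.420320058539
0.608038797496 0.608581750384 0.509820629083
-0.152478622310 -0.832463012200 0.532687153080
-0.785323564821 0.272826793568 0.555726946665
0.795574111193 -0.108016553697 0.596149526316
-0.105837449629 0.792049795752 0.601211739161
0.271714353023 -0.750053579095 0.602985023734
-0.509453251292 0.613876923479 0.603002908424
0.600435019525 -0.498864173863 0.624989858609
-0.677028545993 -0.162228324368 0.717853967520
-0.414488282032 -0.528980083490 0.740526525743
0.271024389673 0.562217803505 0.781317426930
0.553953140735 0.211045997378 0.805354272889
-0.466151936467 0.192742948030 0.863453836700
0.037892312844 -0.491864904278 0.869846589099
-0.137431231557 0.443932332904 0.885458491627
0.390115481212 -0.222716439572 0.893424478545
-0.222738076111 -0.158849153563 0.961849622271
0.129485122623 0.110299258479 0.985427661779
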