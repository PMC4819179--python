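0.035583610883 -0.999155604386 0.020539835966
0.772898627496 -0.633697532636 0.032483053196
0.424107718446 -0.904923732485 0.035294213967
0.963775535570 -0.261334569878 0.053300653128
-0.318337407323 -0.946379892253 0.055012677062
0.982192631993 0.168701857539 0.082688070002
0.836511535073 0.539814673899 0.094066835453
0.590362678325 0.793094462961 0.149910242683
-0.891424456611 -0.389039718196 0.232401669147
-0.602832888807 -0.762723273834 0.234191621806
-0.967199751021 0.012718125883 0.253698425103
-0.865273812384 0.426253554616 0.263835435033
-0.577200436713 0.768282819246 0.276733022079
-0.199641598050 0.934254458785 0.295485767117
0.265584019989 0.908528376743 0.322554362829
0.584605417375 -0.738768517021 0.335346960973
0.207321013529 -0.908254003997 0.363445541413
0.926714801764 -0.070261919278 0.369138102734
0.812870537040 -0.436430063348 0.385707518488
-0.186105652830 -0.903311173468 0.386514695546
0.843116444469 0.330521646791 0.424158109753
0.607566701508 0.638795954801 0.472019524330
-0.677575933013 -0.544323507346 0.494573325557
-0.645322183072 0.522196809111 0.557556968022
-0.804331112279 0.187091322959 0.563957710022
-0.802448181573 -0.187891183212 0.566368977931
0.034098241212 0.822522605244 0.567709321580
-0.332506008212 0.723608129435 0.604839672573
-0.358281561358 -0.693043735209 0.625559512659
0.405475872915 -0.661324219712 0.631062273398
0.748962794557 0.006586817958 0.662579313138
0.037076023630 -0.737595680980 0.674223983459
0.626371474491 -0.355799652036 0.693588771215
0.325561061726 0.633683297914 0.701751717514
0.587146496840 0.339494846680 0.734848447183
-0.507861201535 -0.360286443799 0.782477270207
-0.572487894919 0.043911501566 0.818736459553
-0.420854150284 0.385546837706 0.821118395923
-0.044236823066 0.553944284191 0.831377671998
0.265131721486 -0.414171204071 0.870728076945
-0.121229204250 -0.466325970490 0.876266836805
0.458296833265 -0.042797516023 0.887768204681
0.255828925049 0.294833673625 0.920665338766
-0.270543147290 -0.126234506222 0.954395753811
-0.124159891100 0.214329523230 0.968838055051
0.106055174692 -0.098015384428 0.989517702892
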