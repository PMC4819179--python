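-0.418615539575 0.908156434759 0.003594444652
-0.860006657097 0.507434594245 0.053839412251
0.051289020613 0.996862527454 0.060287127332
-0.970517452546 0.233221485894 0.060857315255
0.635551943180 -0.768576627611 0.073237251520
-0.299216040920 -0.951131963204 0.076274172749
0.864343168456 0.493961931928 0.094406021788
-0.992407859190 -0.066384928425 0.103535898585
0.483659031271 0.868916144464 0.105160236587
0.698566303229 0.707093744872 0.109651976523
0.171390718529 -0.978599676518 0.113876664512
0.965470679793 0.228262836533 0.125548571945
-0.924945112825 -0.351791402668 0.143942166409
-0.569362325650 -0.808003898123 0.151513176814
-0.777345038692 -0.609088949278 0.157306524618
0.984858087689 -0.060564040812 0.162439355065
-0.206993144382 0.961507324128 0.180713872814
-0.701508959854 0.688841443151 0.182709182696
0.789070172371 -0.583035570779 0.193488465497
0.921044717786 -0.334919892562 0.198759385703
0.254795405598 0.936127176504 0.242374113089
-0.086385827886 -0.965677005650 0.244960016125
-0.483726596485 0.837552957118 0.253995322548
0.416385661699 -0.868191622725 0.269937561229
-0.875322544284 0.383231281605 0.294863066976
-0.941961161305 0.114321944730 0.315657509883
-0.367972490652 -0.865067246011 0.340961736859
0.853985061516 0.387743611121 0.346935738637
-0.914103108013 -0.179291462903 0.363689536901
0.007289102705 0.931103774765 0.364681545461
0.489542542492 0.791049936189 0.366862504960
0.698071731161 0.612468718158 0.370914986799
0.613159385804 -0.695487978999 0.374609181238
0.919532714750 0.094262197054 0.381541904266
0.156838537411 -0.909612137029 0.384717342153
-0.800189295034 -0.454416358357 0.391411376137
-0.615391716921 -0.682492165093 0.394331686948
-0.714153651497 0.558570043436 0.421881581288
0.882328224432 -0.177602987596 0.435837220952
0.782175647108 -0.442560049180 0.438567965019
-0.255584106596 0.860485735172 0.440727879787
-0.502528859146 0.710143673490 0.493113281840
-0.134834705273 -0.856667234844 0.497936593351
0.235718640738 0.825643432820 0.512591108243
0.381677627430 -0.756571500467 0.530963043347
-0.836704353594 0.033383809512 0.546636392806
-0.778796226479 0.303128659535 0.549171606505
0.785190977180 0.244392951230 0.568987886290
-0.400065886190 -0.711953489078 0.577121751537
-0.762099746773 -0.261758416770 0.592187898575
0.643657551659 0.470573223866 0.603544362225
0.449338847787 0.658649977361 0.603551826434
0.582544278666 -0.536025055444 0.610998611561
-0.605510717693 -0.506387676860 0.613944860295
0.113858991061 -0.778750827859 0.616914320034
-0.021960314932 0.785019970607 0.619081085413
0.766189888643 -0.016259884636 0.642408492077
0.696645840700 -0.278509984191 0.661148063100
-0.563383590889 0.491990099282 0.663735392853
-0.284986175277 0.690628036400 0.664692256040
-0.160832830920 -0.678811676726 0.716482733943
-0.672657245413 -0.032041198813 0.739260165146
0.349303954345 -0.572148899080 0.742046079944
0.202834835129 0.637677669871 0.743118576680
-0.609416824760 0.235963133119 0.756923069742
0.597992578211 0.216251846451 0.771777179833
-0.364312379156 -0.499670504914 0.785879047254
-0.543620454124 -0.287766764143 0.788458680790
0.419603828119 0.441129851331 0.793307684125
0.088304233664 -0.587709718357 0.804238552462
-0.332832871092 0.475485016617 0.814331799019
-0.058152939376 0.571622903391 0.818453109201
0.471174357031 -0.324873057026 0.820031842122
0.553750092728 -0.056275424758 0.830779099022
-0.451116643376 -0.026069388092 0.892084167035
-0.102765260666 -0.426960969880 0.898411727105
-0.372696138218 0.231379821015 0.898643960078
0.165527559232 0.392899715867 0.904560910280
0.205259729523 -0.357526184309 0.911067215396
0.363742143902 0.176617107568 0.914602673331
-0.284750347277 -0.237821734501 0.928632361230
-0.102281846142 0.317236961314 0.942814475030
0.299700280200 -0.097912317407 0.948995742956
-0.176116950700 0.034831376381 0.983752811887
0.010978517321 -0.170280219483 0.985334521373
0.099653430060 0.112383520110 0.988655217093
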