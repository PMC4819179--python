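-0.573639557942 0.819001721681 0.013184742963
-0.911335444300 0.411399870920 0.014759883790
0.570448331764 0.821104776212 0.019381621940
0.909603605996 0.414746848144 0.024623807863
-0.002002035500 0.999534047272 0.030457842969
-0.988729408430 0.106938390331 0.104777562384
0.987136609693 0.110570818018 0.115479037087
-0.304139234830 -0.945547235165 0.115929943973
0.306338338220 -0.944425634612 0.119235243218
-0.770714944055 -0.616175792080 0.162252483078
0.771171676122 -0.613341684053 0.170605464597
-0.757220662007 0.623573595715 0.194352359791
-0.301723703155 0.932477486535 0.198616575489
0.296123876099 0.933576837743 0.201853754075
0.752772912468 0.626349514308 0.202532042353
-0.949896808688 -0.225805912172 0.216119741978
0.948324034093 -0.222315628030 0.226400724147
0.000246678765 -0.959993780056 0.280021215989
-0.554667688719 -0.769890614367 0.315614000007
0.554041239268 -0.767854061040 0.321618479156
-0.882257593663 0.332346952158 0.333417218835
-0.003571844708 0.940347231229 0.340197481834
0.877365696270 0.335582355683 0.342948855608
-0.526534361733 0.772500081651 0.354972097162
0.519814042667 0.774423901292 0.360639684662
-0.912734569183 0.012826323665 0.408351676426
-0.808111591103 -0.422024149945 0.410915165439
0.908204488482 0.016174834309 0.418214038305
0.805159712120 -0.419057144687 0.419653365845
-0.280783786322 -0.862144809528 0.421742566909
0.279364269896 -0.861116556136 0.424775095144
-0.693514579995 0.507447266794 0.511404730872
0.686062569276 0.509984019873 0.518878069023
-0.224059791789 0.823798527710 0.520723722761
0.215375655869 0.824607195682 0.523102570906
-0.593035703452 -0.575046839808 0.563586538571
0.589006926826 -0.572874852137 0.569987055940
-0.001671704835 -0.811717387382 0.584048018937
-0.773941070396 -0.175560024696 0.608435614739
0.767945582705 -0.172724020853 0.616786830780
-0.758745547599 0.189188598411 0.623308004304
0.751248008860 0.191965079429 0.631487004984
-0.434684882147 0.633562900261 0.640036799447
0.425392401185 0.635144373212 0.644695998274
-0.317261786579 -0.675916745002 0.665192838658
0.312521311560 -0.674760498207 0.668602048965
-0.005144740309 0.702645825078 0.711521170555
-0.557892636607 -0.329274307570 0.761796715925
0.550816349634 -0.327236965880 0.767800310718
-0.528027719536 0.347102465868 0.775052646979
0.518320640349 0.349025798760 0.780720632229
-0.003263094725 -0.594208189973 0.804304655700
-0.576497414902 0.004927083476 0.817084117126
0.567590475379 0.007030119848 0.823281015009
-0.225157475548 0.511119834243 0.829494199044
0.214277893990 0.511926197101 0.831875322911
-0.283912596209 -0.434570945132 0.854717340038
0.276235507148 -0.433542596767 0.857749824470
-0.304337474496 0.187949974994 0.933838052618
0.293510086292 0.189047942918 0.937076680173
-0.310110200405 -0.130008551306 0.941769313682
-0.005720359823 0.328360033878 0.944535317304
0.300367388072 -0.128887575956 0.945075354110
-0.004641985855 -0.292064521761 0.956387352016
-0.005448192368 0.017897210095 0.999824988221
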