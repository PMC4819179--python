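-0.300514092138 0.952186108082 0.055071735054
0.456428791530 0.887817119125 0.058766667859
0.993435744479 -0.084804627603 0.076769764413
-0.668318125976 0.735415940750 0.111867227474
-0.792648819871 -0.594601095101 0.134749345311
-0.139079899605 -0.976003480198 0.167552941388
0.928654307773 0.314960732263 0.195961510982
-0.901563618312 0.374555968079 0.216542995529
0.862385625884 -0.453521548263 0.224964969561
-0.953443582316 -0.170053393878 0.249052561864
0.695534097953 0.658394994325 0.287660129375
0.060156632496 0.955726415113 0.288042009127
0.584797673637 -0.746281977153 0.317922775977
0.209644466027 -0.909930819120 0.357875819636
-0.493478078098 -0.778020442747 0.388797604293
-0.354301619518 0.811452659022 0.464774079068
0.870911865215 -0.031110632290 0.490453516233
-0.749713869879 -0.406087769498 0.522514915361
-0.651596918615 0.548840522450 0.523636836527
0.362661164669 0.767904203219 0.528015164858
-0.831462227732 0.117917084019 0.542923682621
0.700223860325 0.389193846598 0.598510396903
-0.122561244799 -0.780810656098 0.612628321739
0.679483597540 -0.399724113166 0.615241963805
0.308408669616 -0.658723061073 0.686271098996
-0.041106278094 0.724427707729 0.688124095041
-0.416477388050 -0.498694322460 0.760164822910
-0.595955554467 -0.099725573830 0.796800970773
0.586511042489 0.050893271714 0.808340690509
-0.483878806442 0.334315819614 0.808760924769
0.331666565013 0.457541107030 0.825017227111
0.358220705334 -0.290801425242 0.887193585046
-0.034592310358 -0.425391449577 0.904348100397
-0.108446727997 0.397914668670 0.910990243441
-0.229829754349 -0.049261693975 0.971983317513
0.171970030142 0.076246960654 0.982146989877
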