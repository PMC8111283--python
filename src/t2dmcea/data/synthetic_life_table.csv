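age,q_background,q_t2dm
40,0.014888060396937353,0.07688365361336424
41,0.01595890807832956,0.08066223401040751
42,0.01710610730222739,0.08461787088999162
43,0.018335001512236215,0.08875796771554889
44,0.019651293045853002,0.09309014386987824
45,0.021061064960411935,0.09762223043741547
46,0.022570803832489217,0.10236226445500762
47,0.024187423514771766,0.10731848145770195
48,0.025918289821356688,0.11249930613335646
49,0.027771246096931712,0.11791334088695293
50,0.029754639606944466,0.12356935210247055
51,0.031877348664305694,0.12947625387723527
52,0.034148810382956696,0.13564308899098265
53,0.036579048919287094,0.14207900685971053
54,0.039178704028397626,0.14879323821303525
55,0.041959059722995184,0.15579506622353423
56,0.04493207277768019,0.16309379380786115
57,0.048110400769887485,0.1706987068127046
58,0.05150742929009111,0.1786190327944559
59,0.0551372978873681,0.18686389510035828
60,0.05901492424131349,0.1954422619615941
61,0.0631560259668843,0.20436289031599997
62,0.06757713936432852,0.21363426409072372
63,0.07229563432128128,0.2232645266940817
64,0.0773297244578316,0.23326140749217295
65,0.082698471477482,0.24363214208055484
66,0.0884217825472281,0.254383386205678
67,0.09452039937855772,0.2655211232460635
68,0.10101587751847207,0.2770505652306978
69,0.10793055418659958,0.2889760474531532
70,0.1152875028126854,0.30130091683585336
71,0.12311047224055494,0.31402741431100367
72,0.13142380837339407,0.32715655161420554
73,0.14025235584541385,0.3406879830347608
74,0.1496213371226004,0.3546198728339919
75,0.1595562062680218,0.3689487592301387
76,0.17008247446471658,0.3836694160556845
77,0.18122550428356576,0.39877471341997905
78,0.1930102696294118,0.41425547895576065
79,0.20546107831364624,0.4301003614908522
80,0.2186012543064061,0.44629569926319423
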