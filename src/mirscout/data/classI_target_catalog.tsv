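id	sugarcane_targets	sorghum_conserved
Seq7	TC130098,TC151912,TC148492,TC113248,TC152641,TC150124,TC132416,TC114872,TC140938,TC115982,TC120001	+
Seq15	No TC found	+
Seq42	TC153375,TC149921,TC131074,TC139079	+
Seq143	No TC found	+
Seq151	TC153350,TC116972,TC137677	+
Seq155	TC152159,TC125281,TC149817,TC136354	+
Seq171	TC149921,TC132416,TC152095,TC148248	+
Seq183	TC149944,TC132416	+
Seq253	No target found	+
Seq313	TC154059,TC139862,TC140501	+
Seq345	No TC found	-
Seq375	TC136870,TC153496,TC134975	+
Seq376	No TC found	-
Seq393	TC152280,TC116268	+
Seq394	No TC found	-
Seq409	TC129500,TC154465,TC152078,TC154496,TC150491,TC154742,TC131475,TC116420,TC142998,TC146859,TC134345,TC133965,TC153566,TC149558,TC149819,TC154535,TC150277	+
Seq468	TC153570,TC141767	+
Seq488	TC152925	-
Seq501	TC151370	-
Seq504	TC126404	+
Seq509	No target found	+
Seq511	TC124067,TC118309	+
Seq513	TC141387	-
Seq536	TC139920,TC130151,TC120175	+
Seq538	No TC found	-
Seq565	No TC found	-
Seq568	No target found	+
Seq587	TC139519,TC152280	+
Seq594	TC115982,TC149921,TC113248,TC140938,TC132416,TC148248,TC140476	+
Seq598	TC124210	+
Seq610	TC122224,TC140470,TC145127,TC142562,TC120001,TC150124	+
Seq648	TC137080,TC134144,TC117196	+
Seq656	No TC found	+
Seq670	TC138461,TC153815,TC149322,TC146441,TC153901,TC142328,TC154437,TC154455,TC125410	+
Seq678	TC133894,TC129132	+
Seq700	TC152242,TC146024,TC117281,TC152372,TC146587,TC153355,TC154348,TC148421,TC128182,TC148979,TC120001,TC117481,TC134335,TC113000,TC138157,TC130788,TC129900	+
Seq720	TC125467,TC129883,TC145851,TC144060	+
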