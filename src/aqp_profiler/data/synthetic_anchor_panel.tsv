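id	subfamily	class	NPA_LB	NPA_LE	H2	H5	LE1	LE2	P1	P2	P3	P4	P5	SDP1	SDP2	SDP3	SDP4	SDP5	SDP6	SDP7	SDP8	SDP9	sequence
RefPIP1;1	PIP	PIP1	85	205	70	190	209	211	213	214	215	216	217	46	48	90	92	126	128	166	168	219	GGYHRDRTYRQYDYSRHDYVILFIFVIVIVFILLILLFVFVVFVHHEPQDQEDQSHQEEFVVVLFLFLIFIIIIILFFVVLFIFNPAHYFRFTKRHYKGLIVVLFVIVLIIFIIFLVFFIFLILELTPKSQRHHRRKQSVIIVIVLIFFLFIVVVFLFFFLLILRGTGKETSDKSGRKHLVVFFFVFILHVFIFVLLFIVLIIINPAETSRGQSAFWTNLLFIFLVVILFFLVIIIVIVVVIFFGKSGRD
RefPIP2;1	PIP	PIP2	85	205	70	190	209	211	213	214	215	216	217	46	48	90	92	126	128	166	168	219	GGYHRDRTQRQQDESRERYVILIIFFIVIIFIILILLFFFLVFVGHEPQDQEDESHGEEFFFVFFLFLIFIIIIIFFFVVLLIFNPAHYFRFTKRHEKGLLVVLFVIVVIIFIVFLVFFIIFILELTPTSQRHHRRKQSVIIIIVLIFFLVIIVVFLFFFLLILRGTGKETSDKSGRKHLVVIFFVFILHVFIFVLLLIVLIIINPAETGRGQSAFWHNLFFIFLFVILFFLVLIIFIVVVIFFQKSGRD
RefTIP1;1	TIP	TIP1	85	205	70	190	209	211	213	214	215	216	217	46	48	90	92	126	128	166	168	219	YEHYKEERGDDSHETDRKHVVLFILVIVLFLIIIVLFVFFIIFLDTRLQYKYEYSRKQEVFIIFLVIFVHLLVFVIFIIIFFLVNPAQSTRVYHSDSGKFLFLLVFLFFIIILLVIVIILIVVIRAGSTHRKHTDSDDRVLIVLVFVLFFFVIIFLIIVLFFVVGHHPGERGGKTSDQEVVVFLFILFLIVIIVIFLLFFVIIINPAQGRRSTSAYWGAIFVFIVILVILIFFLILFILVFVVLHKKTYR
RefTIP2;1	TIP	TIP2	85	205	70	190	209	211	213	214	215	216	217	46	48	90	92	126	128	166	168	219	YEHSKEERGDDSHKTDRKKVVLFILVIVLFLIIIVLFVFFIIFLDTHLQEKSEYSRKQEVFIIFLVIFVHLLVFVILIIIVFLVNPATSTRVYHSDSGKFLFLLVFLFFIVIILLIVIILIVLIRAGSTQRKHTDSDDRIVIVLIFVLFLFVIIFLILVLFFIVGHHPGSRGGKTSEQEILFLLLILFLIVIIVIFLLFFVIIINPAGGRRSTSAYWGAIFVFIVIIVFLIFFLILFIVVLVVIHKDTYR
RefNIP1;1	NIP	NIP1	85	205	70	190	209	211	213	214	215	216	217	46	48	90	92	126	128	166	168	219	TGKTQDYDKRGSKKDQGETFVIIILVLVLIFFIVFFVLLVILFIRFTTREDHQKKEREKVLLVIVLLFVWLLVVIIFFFILVVINPAEKFRTDRRTTYYIVLVLFVFVFLIVIILLLFFIVFIIHAYDRYDDHTYQKETILFIFFFFVLLIILIFFLIVVVVVFRLREQQHHDDHQYQDLFVVIILIFVVFFIIIILILFVVFVNPATAQRTFSAYLRTLIFVFFIVIIILIFVLVVLFVILLVQRREEK
RefNIP4;1	NIP	NIP4	85	205	70	190	209	211	213	214	215	216	217	46	48	90	92	126	128	166	168	219	TGKTQDGDKEGSKKDQGETFVIIVVVLVLIFFIVFFVLLIILFIRFTTREDEQKKEREKVLIFIILLFVWLFVVIIFFFILVVINPAEGFRTDRRTTYTIVLVLFVFVFLIVIIILLFFIVFIFHAYDRYDGHTQSKETIIFVIFFFLLLIIFIIFLIVVVVVFRLREQQHSDDHQYQRLFVVILLILVVFFIIIVLILFVVFVNPATAQRSFSAYLQTLFFVFFIVIIFFFFVLVVLFVILLFGRTDEK
RefSIP1;1	SIP	SIP1	85	205	70	190	209	211	213	214	215	216	217	46	48	90	92	126	128	166	168	219	EEGREHKEHQKRHRHESTYIFVLVLFLVLIVIVIIFLFLVIFVFSARATQEYYTYDQHRVLVLIFIVLIIFLILLFFIFLVIIINPTEKADAQQRKHTGILIVFIVLFVLIVVIIFILILVLFFEAEAKGDDKQHHSTGIIIVFVVLIFVLFIFIIVILLLVLFDAEATSHYRHTYSGHIVILLFIFIFVLIIFVVLFFLIVVINPAGPSIYIAAYWHAFIFFLLVVFVLLFLIIIVIIILLFVHYEGKS
RefSIP2;1	SIP	SIP2	85	205	70	190	209	211	213	214	215	216	217	46	48	90	92	126	128	166	168	219	EEGREHKEHQKRHRDESTYIFILVLFLVLIVIVIIFLFLVIFVFSAQATQEYYTYDQHRVLVLIVIVLIIFFILLFVIFLVFLINPTEKADAQQRKHTGILVVFIVLFVLIVVIIFILVFLLFFEAEAKGDDKQHHSKGIIIVFVVIILFLFFVIIVVLLLILFDAEATSHYRHTYSGHIFILLIIFIFVLVFFIVLLFLIVVINPAGPQIYIAAYWHAFIFFILVVFVVLFLIIIVIVVLLFVHYEQKS
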