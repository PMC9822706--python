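bigram	collocate	node_word	freq_collocate_pm	freq_node_pm	freq_bigram_pm	printed_mi	table_group
Luftleerem Raum	Luftleerem	Raum	0.403	179.922	0.313	12.07	collocation
Zugekniffenen Augen	Zugekniffenen	Augen	0.052	186.364	0.039	11.97	collocation
Mulmiges Gefühl	Mulmiges	Gefühl	1.581	123.234	0.701	11.81	collocation
Spitze Zunge	Spitze	Zunge	8.703	11.540	0.108	10.07	collocation
Niedrigem Blutdruck	Niedrigem	Blutdruck	63.948	6.629	0.425	9.97	collocation
Beruflichen Tätigkeit	Beruflichen	Tätigkeit	57.828	67.397	2.249	9.17	collocation
Gestellten Fragen	Gestellten	Fragen	16.690	468.665	3.116	8.64	collocation
Verheirateten Frauen	Verheirateten	Frauen	3.728	484.008	0.424	7.88	collocation
Dunkle Haare	Dunkle	Haare	61.371	57.298	0.709	7.66	collocation
Allerletzte Chance	Allerletzte	Chance	2.483	148.129	0.067	7.50	collocation
Harmonische Beziehung	Harmonische	Beziehung	15.426	85.785	0.181	7.10	collocation
Positiven Denkens	Positiven	Denkens	144.827	31.704	0.607	7.05	collocation
Letztes Mal	Letztes	Mal	548.940	209.305	12.105	6.72	collocation
Dauerhafte Liebe	Dauerhafte	Liebe	37.418	158.959	0.018	1.63	non_collocation
Herrliches Gefühl	Herrliches	Gefühl	43.970	123.234	0.132	4.61	non_collocation
Erhaltenen Sätze	Erhaltenen	Sätze	0.008	101.133	0	0	non_collocation
Imposante Geste	Imposante	Geste	8.223	8.452	0.001	3	non_collocation
Stilvoller Verlierer	Stilvoller	Verlierer	8.677	6.194	0	0	non_collocation
Realen Umgebungen	Realen	Umgebungen	36.225	73.968	0.076	4.83	non_collocation
Allfälligen Treffen	Allfälligen	Treffen	3.824	39.096	0.001	0	non_collocation
Quirlige Person	Quirlige	Person	2.327	248.850	0.002	0	non_collocation
Markanten Anlass	Markanten	Anlass	9.582	52.683	0	0	non_collocation
Lustlosesten Antwort	Lustlosesten	Antwort	1.269	141.288	0	0	non_collocation
Schöne Homepage	Schöne	Homepage	491.246	53.832	0.177	2.74	non_collocation
Ersehnte Meldung	Ersehnte	Meldung	4.753	32.984	0.001	2.89	non_collocation
Zielstrebige Art	Zielstrebige	Art	2.770	258.706	0	0	non_collocation
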