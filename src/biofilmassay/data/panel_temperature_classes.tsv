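isolate_id	level	class_24h	class_48h
A2.48.2016	4	NP	NP
A2.48.2016	10	NP	NP
A2.48.2016	20	NP	NP
A2.48.2016	37	NP	WP
N9.25.2016	4	NP	WP
N9.25.2016	10	NP	NP
N9.25.2016	20	NP	NP
N9.25.2016	37	NP	NP
A1.6.2017	4	NP	NP
A1.6.2017	10	NP	NP
A1.6.2017	20	WP	WP
A1.6.2017	37	WP	WP
N10.27.2017	4	NP	NP
N10.27.2017	10	NP	NP
N10.27.2017	20	NP	NP
N10.27.2017	37	NP	NP
A4.16.2019	4	NP	NP
A4.16.2019	10	NP	NP
A4.16.2019	20	NP	WP
A4.16.2019	37	WP	MP
N9.1.2019	4	NP	NP
N9.1.2019	10	NP	NP
N9.1.2019	20	NP	WP
N9.1.2019	37	MP	MP
A4.26.2021	4	NP	NP
A4.26.2021	10	NP	NP
A4.26.2021	20	NP	NP
A4.26.2021	37	MP	WP
N10.1.2021	4	NP	NP
N10.1.2021	10	NP	WP
N10.1.2021	20	NP	WP
N10.1.2021	37	NP	WP
A1.14.2022	4	MP	MP
A1.14.2022	10	MP	MP
A1.14.2022	20	MP	WP
A1.14.2022	37	SP	SP
N10.55.2022	4	NP	NP
N10.55.2022	10	NP	NP
N10.55.2022	20	NP	WP
N10.55.2022	37	WP	MP
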