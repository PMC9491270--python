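surface	language	score_1	score_2	review_label
depressed	en	5	5	0
depression	en	5	5	0
anxiety	en	5	4	0
hopeless	en	5	5	0
lonely	en	4	4	0
sad	en	4	5	0
suicidal	en	5	5	0
insomnia	en	4	3	0
worthless	en	5	4	0
tired	en	3	4	0
empty	en	4	3	0
crying	en	4	4	0
pain	en	3	4	0
hurt	en	3	3	0
fear	en	3	4	0
stress	en	4	4	0
misery	en	5	4	0
gloomy	en	4	4	0
helpless	en	5	4	0
despair	en	5	5	0
anguish	en	4	4	0
fatigue	en	3	4	0
grief	en	4	4	0
sorrow	en	4	5	0
numb	en	4	3	0
broken	en	3	3	0
overwhelmed	en	4	4	0
isolation	en	4	3	0
medication	en	3	3	0
therapy	en	3	4	0
panic	en	4	4	0
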