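group	animal	replicate	identified_proteins
sham	sham_1	1	305
sham	sham_1	2	324
sham	sham_1	3	337
sham	sham_2	1	254
sham	sham_2	2	253
sham	sham_2	3	265
sham	sham_3	1	269
sham	sham_3	2	266
sham	sham_3	3	278
uuo1w	uuo1w_1	1	233
uuo1w	uuo1w_1	2	240
uuo1w	uuo1w_1	3	249
uuo1w	uuo1w_2	1	191
uuo1w	uuo1w_2	2	194
uuo1w	uuo1w_2	3	197
uuo1w	uuo1w_3	1	271
uuo1w	uuo1w_3	2	275
uuo1w	uuo1w_3	3	265
uuo3w	uuo3w_1	1	222
uuo3w	uuo3w_1	2	216
uuo3w	uuo3w_1	3	236
uuo3w	uuo3w_2	1	275
uuo3w	uuo3w_2	2	273
uuo3w	uuo3w_2	3	275
uuo3w	uuo3w_3	1	275
uuo3w	uuo3w_3	2	289
uuo3w	uuo3w_3	3	288
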