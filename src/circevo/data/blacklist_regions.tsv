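species	chrom	start	end	strand
macaque	7	164261342	164283671	+
macaque	7	22010813	22092409	-
macaque	19	52240849	52288425	-
macaque	19	59790995	59834798	+
macaque	19	59790995	59847609	+
human	2	178535730	178600667	+
human	7	66429677	66490107	-
human	9	97185440	97211487	-
human	12	97492459	97561047	+
human	14	100913430	100949596	+
human	18	21765770	21849388	+
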