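# Surface -> lemma dictionary: noun/gerund forms of action verbs and
# irregular inflections that plain suffix stripping cannot recover.
addition	add
additions	add
stirring	stir
mixing	mix
removal	remove
dissolution	dissolve
transferral	transfer
held	hold
kept	keep
heating	heat
cooling	cool
washing	wash
refluxing	reflux
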