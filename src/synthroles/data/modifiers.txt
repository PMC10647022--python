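# MODIFIER lexicon: atmosphere, dosing mode, parallel actions.
dropwise
portionwise
in one portion
in portions
under nitrogen
under argon
with stirring
with vigorous stirring
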