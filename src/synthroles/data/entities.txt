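# ENTITY lexicon: one phrase per line, matched case-insensitively on tokens.
# A matched phrase absorbs directly following parenthesized amount/coreference
# groups such as "(150 mL)" or "(1)" into the same span.
DMF
THF
anhydrous CH2Cl2
dichloromethane
toluene
acetonitrile
methanol
benzaldehyde
sodium hydride
triethylamine
potassium carbonate
12-aminododecanolactam
aqueous NaHCO3
diethyl ether
nitrogen gas
argon gas
aluminum foil
the flask
the round-bottomed flask
the reaction vessel
the three-necked flask
the mixture
the reaction mixture
the solution
the suspension
the ice bath
the precipitate
the solid
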