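# Roleset registry: lemma<TAB>sense<TAB>origin_type<TAB>arg0_desc<TAB>arg1_desc<TAB>arg2_desc
# An empty description field means the slot is absent. One roleset per lemma.
# Origin types: A = PropBank as-is / lightly reworded; B = argument definitions
# changed from PropBank; C = new roleset, verb in PropBank; D = new roleset,
# verb not in PropBank.
add	01	A		thing being added	thing being added to
stir	01	A		thing stirred
charge	01	C		vessel being charged	material charged into the vessel
cool	01	C		thing cooled	instrument used for cooling
heat	01	A		thing heated	instrument used for heating
mix	01	B		ingredient
hold	01	A		thing held at a condition
contain	01	A	container	thing contained
remove	01	A		thing removed	thing removed from
backfill	01	D		vessel backfilled	gas introduced
place	01	A		thing placed	location placed into
reflux	01	C		mixture refluxed
transfer	01	A		thing transferred	destination vessel
dissolve	01	A		solute dissolved	solvent
fill	01	A		container filled	substance used to fill
wrap	01	A		thing wrapped	wrapping material
wash	01	A		thing washed	washing liquid
open	01	A		thing opened
activate	01	C		material activated
keep	01	A		thing kept at a condition
maintain	01	A		condition maintained
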