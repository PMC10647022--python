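# TEMPERATURE word expressions (non-numeric); "room temperature" additionally
# absorbs a following parenthesized value, e.g. "room temperature (23 °C)".
room temperature
ice/water
ice-water
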