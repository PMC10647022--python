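# TEMP_TARGET phrases: the place where a temperature is maintained.
internal temperature
bath temperature
external temperature
reaction temperature
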