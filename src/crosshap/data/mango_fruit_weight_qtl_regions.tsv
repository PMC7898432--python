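region_id	lg	start_bp	end_bp
LG4:8275233-8495231	LG4	8275233	8495231
LG7:3831615-3914160	LG7	3831615	3914160
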