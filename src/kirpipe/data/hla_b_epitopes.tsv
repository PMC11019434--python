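allele	epitope
B*07:02	Bw6
B*07:05	Bw6
B*08:01	Bw6
B*14:01	Bw6
B*14:02	Bw6
B*15:01	Bw6
B*15:03	Bw6
B*18:01	Bw6
B*35:01	Bw6
B*35:02	Bw6
B*35:03	Bw6
B*35:08	Bw6
B*39:01	Bw6
B*39:06	Bw6
B*40:01	Bw6
B*40:02	Bw6
B*41:01	Bw6
B*41:02	Bw6
B*42:01	Bw6
B*45:01	Bw6
B*46:01	Bw6
B*48:01	Bw6
B*50:01	Bw6
B*54:01	Bw6
B*55:01	Bw6
B*55:02	Bw6
B*56:01	Bw6
B*67:01	Bw6
B*78:01	Bw6
B*81:01	Bw6
B*51:01	Bw4-80I
B*51:08	Bw4-80I
B*52:01	Bw4-80I
B*53:01	Bw4-80I
B*57:01	Bw4-80I
B*57:03	Bw4-80I
B*58:01	Bw4-80I
B*58:02	Bw4-80I
B*13:01	Bw4-80T
B*13:02	Bw4-80T
B*27:05	Bw4-80T
B*37:01	Bw4-80T
B*44:02	Bw4-80T
B*44:03	Bw4-80T
B*44:05	Bw4-80T
B*47:01	Bw4-80T
B*49:01	Bw4-80T
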