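allele	epitope
C*01:02	C1
C*03:02	C1
C*03:03	C1
C*03:04	C1
C*07:01	C1
C*07:02	C1
C*07:04	C1
C*07:06	C1
C*08:01	C1
C*08:02	C1
C*12:02	C1
C*12:03	C1
C*14:02	C1
C*14:03	C1
C*16:01	C1
C*02:02	C2
C*04:01	C2
C*04:03	C2
C*05:01	C2
C*06:02	C2
C*15:02	C2
C*15:05	C2
C*17:01	C2
C*17:03	C2
C*18:01	C2
C*18:02	C2
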