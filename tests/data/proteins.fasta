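>DEER1
AAAAAAKDDDDDDKSSSSSSKMMMMMMK
>DEER2
EEEEEEKLLLLLLK
>SALM1
FFFFFFKHHHHHHKMMMMMMKNNNNNNK
>SALM2
PPPPPPK
>KERA1
GGGGGGKYYYYYYR
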