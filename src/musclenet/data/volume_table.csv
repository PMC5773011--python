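group,volume_mm3,source
Thumb,1390,Indovina (2000)
Index,1000,Indovina (2000)
Middle,650,Indovina (2000)
Hand,5566,Alkadhi (2002)
Fingers,2972,Alkadhi (2002)
Wrist,4409,Alkadhi (2002)
Elbow,2267,Alkadhi (2002)
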