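session,clinician,positive,negative
week0,A,39,61
week0,B,41,59
week0,C,30,70
week0,D,32,68
week0,E,42,58
week0,F,50,50
week0,G,37,63
week0,H,42,58
week0,I,39,61
week0,J,53,47
week2,A,41,59
week2,B,48,52
week2,C,41,59
week2,D,49,51
week2,E,44,56
week2,F,46,54
week2,G,42,58
week2,H,46,54
week2,I,52,48
week2,J,43,57
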