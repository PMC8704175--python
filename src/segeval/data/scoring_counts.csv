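session,clinician,arm,score,count
week0,A,AI,0,0
week0,B,AI,0,0
week0,C,AI,0,1
week0,D,AI,0,0
week0,E,AI,0,0
week0,F,AI,0,0
week0,G,AI,0,0
week0,H,AI,0,0
week0,I,AI,0,0
week0,J,AI,0,0
week0,A,AI,1,1
week0,B,AI,1,0
week0,C,AI,1,7
week0,D,AI,1,0
week0,E,AI,1,0
week0,F,AI,1,0
week0,G,AI,1,1
week0,H,AI,1,17
week0,I,AI,1,0
week0,J,AI,1,0
week0,A,AI,2,6
week0,B,AI,2,25
week0,C,AI,2,27
week0,D,AI,2,3
week0,E,AI,2,37
week0,F,AI,2,3
week0,G,AI,2,12
week0,H,AI,2,11
week0,I,AI,2,18
week0,J,AI,2,6
week0,A,AI,3,43
week0,B,AI,3,25
week0,C,AI,3,15
week0,D,AI,3,47
week0,E,AI,3,13
week0,F,AI,3,47
week0,G,AI,3,37
week0,H,AI,3,22
week0,I,AI,3,32
week0,J,AI,3,44
week0,A,GT,0,0
week0,B,GT,0,0
week0,C,GT,0,1
week0,D,GT,0,0
week0,E,GT,0,0
week0,F,GT,0,0
week0,G,GT,0,0
week0,H,GT,0,0
week0,I,GT,0,0
week0,J,GT,0,0
week0,A,GT,1,1
week0,B,GT,1,0
week0,C,GT,1,11
week0,D,GT,1,0
week0,E,GT,1,3
week0,F,GT,1,0
week0,G,GT,1,1
week0,H,GT,1,13
week0,I,GT,1,0
week0,J,GT,1,0
week0,A,GT,2,13
week0,B,GT,2,22
week0,C,GT,2,27
week0,D,GT,2,11
week0,E,GT,2,36
week0,F,GT,2,8
week0,G,GT,2,15
week0,H,GT,2,20
week0,I,GT,2,23
week0,J,GT,2,5
week0,A,GT,3,36
week0,B,GT,3,28
week0,C,GT,3,11
week0,D,GT,3,39
week0,E,GT,3,11
week0,F,GT,3,42
week0,G,GT,3,34
week0,H,GT,3,17
week0,I,GT,3,27
week0,J,GT,3,45
week2,A,AI,0,0
week2,B,AI,0,0
week2,C,AI,0,0
week2,D,AI,0,0
week2,E,AI,0,0
week2,F,AI,0,0
week2,G,AI,0,0
week2,H,AI,0,15
week2,I,AI,0,0
week2,J,AI,0,0
week2,A,AI,1,0
week2,B,AI,1,0
week2,C,AI,1,1
week2,D,AI,1,0
week2,E,AI,1,4
week2,F,AI,1,0
week2,G,AI,1,0
week2,H,AI,1,8
week2,I,AI,1,0
week2,J,AI,1,0
week2,A,AI,2,7
week2,B,AI,2,27
week2,C,AI,2,25
week2,D,AI,2,4
week2,E,AI,2,37
week2,F,AI,2,3
week2,G,AI,2,11
week2,H,AI,2,11
week2,I,AI,2,15
week2,J,AI,2,12
week2,A,AI,3,43
week2,B,AI,3,23
week2,C,AI,3,24
week2,D,AI,3,46
week2,E,AI,3,9
week2,F,AI,3,47
week2,G,AI,3,39
week2,H,AI,3,16
week2,I,AI,3,35
week2,J,AI,3,38
week2,A,GT,0,0
week2,B,GT,0,0
week2,C,GT,0,0
week2,D,GT,0,0
week2,E,GT,0,0
week2,F,GT,0,0
week2,G,GT,0,0
week2,H,GT,0,10
week2,I,GT,0,0
week2,J,GT,0,0
week2,A,GT,1,1
week2,B,GT,1,0
week2,C,GT,1,4
week2,D,GT,1,0
week2,E,GT,1,8
week2,F,GT,1,0
week2,G,GT,1,0
week2,H,GT,1,16
week2,I,GT,1,0
week2,J,GT,1,0
week2,A,GT,2,7
week2,B,GT,2,32
week2,C,GT,2,34
week2,D,GT,2,5
week2,E,GT,2,36
week2,F,GT,2,13
week2,G,GT,2,13
week2,H,GT,2,10
week2,I,GT,2,14
week2,J,GT,2,12
week2,A,GT,3,42
week2,B,GT,3,18
week2,C,GT,3,12
week2,D,GT,3,45
week2,E,GT,3,6
week2,F,GT,3,37
week2,G,GT,3,37
week2,H,GT,3,14
week2,I,GT,3,36
week2,J,GT,3,38
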