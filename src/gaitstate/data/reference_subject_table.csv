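subject_id,tp,fp,fn,tn,on_samples,off_samples,on_windows,off_windows
Subject 1,15,2,1,15,5370,5217,17,16
Subject 2,17,1,1,16,5774,5471,18,17
Subject 3,14,2,1,17,5138,5883,16,18
Subject 4,17,3,2,17,6264,6214,20,19
Subject 5,15,2,2,19,5508,6749,17,21
Subject 6,16,1,1,21,5438,6883,17,22
Subject 7,19,1,2,17,6282,5972,20,19
Subject 8,17,4,1,16,6640,5347,21,17
Subject 9,17,1,2,17,5845,5987,18,19
Subject 10,19,1,2,15,6321,5465,20,17
Subject 11,18,0,1,19,5792,6321,18,20
Subject 12,17,1,2,19,5795,6784,18,21
Subject 13,19,2,1,15,6795,5039,21,16
Subject 14,13,1,2,19,4499,6742,14,21
Subject 15,19,1,0,17,6461,5398,20,17
Subject 16,21,2,0,17,7293,5418,23,17
Subject 17,14,2,2,18,5007,6472,16,20
Subject 18,20,1,1,18,6608,6128,21,19
Subject 19,16,1,2,16,5510,5890,17,18
Subject 20,20,2,1,15,6912,5128,22,16
Total,342,31,27,343,119252,118508,373,370
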