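group,weeks_recovery,source
Triceps brachii,4,Bateman (1962)
Thumb muscles,4,Rettig (2004)
Latissimus dorsi,12,Nagda (2011)
Biceps brachii,12,Zafra (2009)
Ankle,2,McCollum (2012)
Neck,0.14,Torg (1982)
Jaw,0,Beachy (2004)
Shoulder,2,Bateman (1962)
Teres major,12,Nagda (2011)
Hip,12,Niemuth (2005)
Eye/eyelid,1.4,Leivo (2015)
Knee,8,Ekstrand (1982)
Elbow,8,Fleisig (2012)
Wrist/hand,1.4,Logan (2004)
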