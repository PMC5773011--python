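category_id,category_name
1,Toes
2,Ankle
3,Knee
4,Hip
5,Trunk
6,Shoulder
7,Elbow
8,Wrist
9,Hand
10,Little finger
11,Ring finger
12,Middle finger
13,Index finger
14,Thumb
15,Neck
16,Brow
17,Eyelid and eyeball
18,Face
19,Lips
20,Jaw
21,Tongue
22,Swallowing
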