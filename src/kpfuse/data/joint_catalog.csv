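joint,depth_index,rgb_index
Left Shoulder,4,11
Left Elbow,5,13
Left Wrist,6,15
Right Shoulder,8,12
Right Elbow,9,14
Right Wrist,10,16
Left Hip,12,23
Left Knee,13,25
Left Ankle,14,27
Right Hip,16,24
Right Knee,17,26
Right Ankle,18,28
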