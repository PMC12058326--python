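# Default 20-segment body model: segment -> source markers/joints averaged
# into it. The joint names follow common BVH skeleton conventions; edit this
# file to match the marker or joint names of your own capture system (the
# exact grouping used for any particular dense marker set is a modelling
# choice — pool the markers you consider part of each functional segment).
head: [Head, HeadEnd]
neck: [Neck]
l_shoulder: [LeftShoulder]
r_shoulder: [RightShoulder]
upper_trunk: [Spine2, Spine3]
lower_trunk: [Spine, Spine1]
pelvis: [Hips]
root: [LowerBack]
l_upper_arm: [LeftArm]
l_forearm: [LeftForeArm]
l_hand: [LeftHand, LeftHandEnd]
r_upper_arm: [RightArm]
r_forearm: [RightForeArm]
r_hand: [RightHand, RightHandEnd]
l_thigh: [LeftUpLeg]
l_shank: [LeftLeg]
l_foot: [LeftFoot, LeftToeBase]
r_thigh: [RightUpLeg]
r_shank: [RightLeg]
r_foot: [RightFoot, RightToeBase]
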