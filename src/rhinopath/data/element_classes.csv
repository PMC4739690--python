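element,functional,developmental
scapula,forelimb,girdle
humerus,forelimb,stylopod
radius,forelimb,zeugopod
ulna,forelimb,zeugopod
radioulna,forelimb,zeugopod
radius-ulna,forelimb,zeugopod
carpal,forelimb,autopod
metacarpal,forelimb,autopod
pisiform,forelimb,autopod
lunar,forelimb,autopod
scaphoid,forelimb,autopod
magnum,forelimb,autopod
trapezoid,forelimb,autopod
unciform,forelimb,autopod
pelvis,hindlimb,girdle
innominate,hindlimb,girdle
femur,hindlimb,stylopod
tibia,hindlimb,zeugopod
fibula,hindlimb,zeugopod
tibiofibula,hindlimb,zeugopod
patella,hindlimb,other
astragalus,hindlimb,autopod
calcaneum,hindlimb,autopod
calcanium,hindlimb,autopod
calcaneus,hindlimb,autopod
navicular,hindlimb,autopod
cuboid,hindlimb,autopod
tarsal,hindlimb,autopod
metatarsal,hindlimb,autopod
ectocuneiform,hindlimb,autopod
mesocuneiform,hindlimb,autopod
cuneiform,indeterminate,autopod
metapodial,indeterminate,autopod
phalanx,indeterminate,autopod
podial,indeterminate,autopod
sesamoid,indeterminate,other
sesimoid,indeterminate,other
limb bone,indeterminate,indeterminate
axis,axial,other
atlas,axial,other
vertebra,axial,other
centrum,axial,other
rib,axial,other
sacrum,axial,other
skull,axial,other
mandible,axial,other
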