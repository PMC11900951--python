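# HOOS-12 extraction map: which HOOS items form each 12-item short-form scale.
#   scale   - short-form scale name (pain / function / qol)
#   item_id - HOOS item contributing to that scale
scale,item_id
pain,P2
pain,P4
pain,P6
pain,P8
function,A3
function,A6
function,A10
function,A15
qol,Q1
qol,Q2
qol,Q3
qol,Q4
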