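# Instrument rubric, one row per response option.
#   item_id  - short key identifying the question
#   domain   - scoring domain the item belongs to
#   retained - 'true' if the item contributes to the total (the mHHS
#              public-transport item is kept for validation but excluded)
#   code     - integer response code as recorded on the form (0 = best)
#   points   - points awarded for that response
item_id,domain,retained,code,points
pain,pain,true,0,44
pain,pain,true,1,40
pain,pain,true,2,30
pain,pain,true,3,20
pain,pain,true,4,10
pain,pain,true,5,0
limp,gait,true,0,11
limp,gait,true,1,8
limp,gait,true,2,5
limp,gait,true,3,0
support,gait,true,0,11
support,gait,true,1,7
support,gait,true,2,5
support,gait,true,3,3
support,gait,true,4,2
support,gait,true,5,0
walk_distance,gait,true,0,11
walk_distance,gait,true,1,8
walk_distance,gait,true,2,5
walk_distance,gait,true,3,2
walk_distance,gait,true,4,0
stairs,activities,true,0,4
stairs,activities,true,1,2
stairs,activities,true,2,1
stairs,activities,true,3,0
shoes_socks,activities,true,0,4
shoes_socks,activities,true,1,2
shoes_socks,activities,true,2,0
sitting,activities,true,0,5
sitting,activities,true,1,3
sitting,activities,true,2,0
public_transport,activities,false,0,1
public_transport,activities,false,1,0
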