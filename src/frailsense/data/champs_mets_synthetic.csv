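activity_id,activity,met
walk_errands,Walk to do errands,3.0
walk_leisure,Walk leisurely for exercise or pleasure,3.5
walk_fast,Walk fast or briskly for exercise,5.0
walk_uphill,Walk uphill or hike uphill,6.0
jog_run,Jog or run,6.0
cycling,Ride a bicycle or stationary cycle,4.0
swimming_mod,Swim moderately or fast,6.0
swimming_gentle,Swim gently,3.5
water_exercise,Do water exercises,3.0
dance,Dance (square; folk; line; ballroom),4.5
golf_walk,Play golf walking and carrying clubs,4.5
golf_cart,Play golf riding a cart,2.5
tennis_singles,Play singles tennis,6.0
tennis_doubles,Play doubles tennis,5.0
skate,Skate (ice; roller; in-line),5.5
aerobics,Do aerobics or aerobic dancing,5.0
stretching,Do stretching or flexibility exercises,1.5
yoga_taichi,Do yoga or tai-chi,2.5
strength_light,Do light strength training (hand weights),2.5
strength_heavy,Do moderate-to-heavy strength training,4.0
general_conditioning,Do general conditioning exercises,3.5
basketball,Shoot baskets or play basketball,5.5
bowling,Bowl,3.0
gardening_light,Do light gardening (watering; pruning),2.5
gardening_heavy,Do heavy gardening (digging; spading),4.5
housework_light,Do light housework (dusting; sweeping),2.5
housework_heavy,Do heavy housework (scrubbing; moving furniture),4.0
stairs,Climb stairs for exercise,5.5
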