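analysis,model,df,LL,AICc,n
trip_frequency,~ sex + mass,4,46.24,-81.40,18
trip_frequency,~ sex,3,43.53,-79.35,18
trip_frequency,~ sex + mass + length,5,46.35,-77.69,18
trip_frequency,~ 1,2,39.84,-74.88,18
trip_distance,~ sex + week + (1 | id),5,-99.38,209.71,69
trip_distance,~ week + (1 | id),4,-101.04,210.71,69
trip_distance,~ sex + length + week + (1 | id),6,-98.88,211.11,69
trip_distance,~ sex + mass + length + week + (1 | id),7,-98.87,213.58,69
trip_distance,~ sex + mass + length + week + sex*week + (1 | id),8,-97.96,214.32,69
trip_distance,~ (1 | id),3,-106.09,218.54,69
trip_duration,~ sex + week + (1 | id),5,-96.47,203.89,69
trip_duration,~ sex + mass + week + (1 | id),6,-96.25,205.85,69
trip_duration,~ week + (1 | id),4,-99.08,206.78,69
trip_duration,~ sex + mass + length + week + (1 | id),7,-96.17,208.17,69
trip_duration,~ sex + mass + length + week + sex*week + (1 | id),8,-95.22,208.85,69
trip_duration,~ (1 | id),3,-106.86,220.09,69
haulout_duration,~ mass + (1 | id),4,-99.00,206.66,66
haulout_duration,~ mass + week + (1 | id),5,-98.86,208.72,66
haulout_duration,~ (1 | id),3,-101.41,209.21,66
haulout_duration,~ mass + duration + week + (1 | id),6,-98.59,210.61,66
haulout_duration,~ mass + length + duration + week + (1 | id),7,-98.53,212.99,66
haulout_duration,~ sex + mass + length + duration + week + (1 | id),8,-98.50,215.52,66
haulout_duration,~ sex + mass + length + duration + distance + week + (1 | id),9,-98.49,218.20,66
haulout_duration,~ sex + mass + length + duration + distance + week + sex*duration + (1 | id),10,-97.57,220.84,66
haulout_duration,~ sex + mass + length + duration + distance + week + sex*duration + sex*distance + (1 | id),11,-97.65,222.19,66
haulout_duration,~ sex + mass + length + duration + distance + week + sex*duration + sex*distance + sex*week + (1 | id),12,-98.42,225.04,66
move_persistence,~ sex + mass + length + postwean + week + distshore + depth + (1 | id),13,17473.49,-34920.91,5826
move_persistence,~ sex + length + postwean + week + distshore + depth + (1 | id),12,17469.18,-34914.32,5826
move_persistence,~ sex + length + postwean + distshore + depth + (1 | id),11,17460.32,-34898.59,5826
move_persistence,~ length + postwean + distshore + depth + (1 | id),10,17453.32,-34886.60,5826
move_persistence,~ length + distshore + depth + (1 | id),9,17451.14,-34884.26,5826
move_persistence,~ distshore + depth + (1 | id),8,17449.32,-34882.61,5826
move_persistence,~ depth + (1 | id),7,17415.84,-34817.66,5826
move_persistence,~ (1 | id),6,17376.96,-34741.90,5826
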