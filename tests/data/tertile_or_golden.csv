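model_id,model,tertile,estimate,ci_low,ci_high,p_value,trend_p,beta,separated,percent_explained,group
1,base,2,1.0794119160828106,0.49738528383333963,2.3425101675745763,0.8467207937169374,0.01825093618229615,0.07641637068455945,False,,all
1,base,3,2.5683701784780264,1.1709776755613421,5.633348535473158,0.01858087612581431,0.01825093618229615,0.9432715259367039,False,,all
2,BMI,2,1.1304594738281022,0.5135423031716896,2.4884778022667864,0.7606754360306538,0.020740092434327246,0.12262416408634629,False,-64.28198721720713,all
2,BMI,3,2.571003527078385,1.1538101403834844,5.728896726503507,0.020891392659467937,0.020740092434327246,0.9442963001530507,False,-0.16790351133264558,all
1,base,2,0.994384266557234,0.4179652430301778,2.36574711908563,0.9898392992862961,0.06470406837828563,-0.005631560957030407,False,,ses_cohorts
1,base,3,2.289256091419296,0.970007560271944,5.402734645316692,0.05869679352073878,0.06470406837828563,0.8282269138820577,False,,ses_cohorts
2,BMI,2,1.0820608944196632,0.44617177375536154,2.624226470844093,0.8614862247348152,0.0618130218992269,0.0788674583412711,False,,ses_cohorts
2,BMI,3,2.3500940727555495,0.9754125657466843,5.662160140999331,0.05684813868242422,0.0618130218992269,0.8544553583146584,False,-4.718843815527684,ses_cohorts
3,SES,2,0.9169956540715428,0.3380336709876901,2.487565889898342,0.8648658148139112,0.2497411682094982,-0.086652546026387,False,,ses_cohorts
3,SES,3,1.8381582620913155,0.6688973983856377,5.05133643014497,0.23787942242043214,0.2497411682094982,0.6087641258258133,False,34.98900120234321,ses_cohorts
4,BMI+SES,2,0.9660330263126368,0.34770914105871725,2.68390933032491,0.9471518098603879,0.2838123954756966,-0.03455725662460271,False,,ses_cohorts
4,BMI+SES,3,1.7790173168102388,0.6345437788635768,4.98768204642841,0.27342634571062496,0.2838123954756966,0.5760611426499479,False,39.57621592831519,ses_cohorts
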