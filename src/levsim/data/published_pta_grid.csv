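crcl,total_daily_dose,dose_mg,tau_h,tinf_h,p_gt_12,p_gt_46,p_gt_46_bound,p_gt_46_printed
160,3000,1500,12,0.5,51,0.5,1,0
160,3000,1500,12,4,62,0.5,1,<0.5
160,3000,1500,12,6,70,0.5,1,<0.5
160,3000,1000,8,0.5,65,0.5,1,0
160,3000,1000,8,4,81,0.5,1,<0.5
160,3000,1000,8,6,88,1,0,1
160,3000,3000,24,24,98,1,0,1
160,4500,1500,8,0.5,89,5,0,5
200,3000,1000,8,6,69,0.5,1,<0.5
200,3000,3000,24,24,89,0.5,1,<0.5
200,4500,1500,8,4,84,1,0,1
200,4500,1500,8,6,92,2,0,2
200,6000,2000,8,0.5,84,5,0,5
240,3000,3000,24,24,68,0.5,1,<0.5
240,4500,1500,8,4,61,0.5,1,<0.5
240,4500,1500,8,6,74,0.5,1,<0.5
240,4500,4500,24,24,96,1,0,1
240,6000,2000,8,4,80,2,0,2
240,6000,2000,8,6,89,3,0,3
240,6000,6000,24,24,99,7,0,7
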