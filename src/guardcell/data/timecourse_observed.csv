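treatment_aba_um,treatment_acc_um,variable,time_min,mean_pct,sem_pct,source
10,0,ros,0,100,5,percent-of-control convention at stimulus onset
10,0,ros,5,125,5,initial 25 percent ROS rise by 5 min under all treatments
10,0,ros,15,125,5,elevated ROS maintained to 30 min under ABA alone
10,0,ros,30,125,5,elevated ROS maintained to 30 min under ABA alone
10,0,ros,60,115,5,ROS about 15 percent above control at 60 min under ABA alone
0,10,ros,0,100,5,percent-of-control convention at stimulus onset
0,10,ros,5,125,5,initial 25 percent ROS rise by 5 min under all treatments
0,10,ros,15,125,5,elevated ROS maintained to 30 min under ACC alone
0,10,ros,30,125,5,elevated ROS maintained to 30 min under ACC alone
0,10,ros,60,100,5,ROS back to about control at 60 min under ACC alone
10,10,ros,0,100,5,percent-of-control convention at stimulus onset
10,10,ros,5,125,5,initial 25 percent ROS rise by 5 min under all treatments
10,10,ros,15,105,5,ROS about 5 percent above control over 15-30 min under combined dose
10,10,ros,30,105,5,ROS about 5 percent above control over 15-30 min under combined dose
10,10,ros,60,80,5,ROS down to 80 percent of control at 60 min under combined dose
10,0,aperture,0,100,5,percent-of-control convention at stimulus onset
10,0,aperture,15,85,5,about 15 percent aperture reduction at 15 min under ABA alone
10,0,aperture,30,70,5,aperture held 30 percent below control over 30-60 min under ABA alone
10,0,aperture,45,70,5,aperture held 30 percent below control over 30-60 min under ABA alone
10,0,aperture,60,70,5,aperture held 30 percent below control over 30-60 min under ABA alone
0,10,aperture,0,100,5,percent-of-control convention at stimulus onset
0,10,aperture,15,80,5,about 20 percent aperture reduction at 15 min under ACC alone
0,10,aperture,30,70,5,aperture 30 percent below control over 30-45 min under ACC alone
0,10,aperture,45,70,5,aperture 30 percent below control over 30-45 min under ACC alone
10,10,aperture,0,100,5,percent-of-control convention at stimulus onset
10,10,aperture,15,75,5,25 percent aperture reduction at 15 min under combined dose
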