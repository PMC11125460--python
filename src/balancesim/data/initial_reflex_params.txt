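com_delay = 0.1
u_base = 0.01
K_L.GM = 4.739229866122558
K_L.IL = 2.8411837861853213
K_L.HM = 3.2138956025529843
K_L.BF = 4.1332483019731985
K_L.RF = 0.3212180922836466
K_L.VAS = 2.851953018054551
K_L.GAS = 4.67141294173823
K_L.SOL = 6.465539123592716
K_L.TA = 8.2731657990558
l_0.GM = 0.743687932935697
l_0.IL = 1.4982109756979827
l_0.HM = 1.0506811062672383
l_0.BF = 1.3821536898504911
l_0.RF = 1.34940695840399
l_0.VAS = 0.7157676026710083
l_0.GAS = 1.3116495630725338
l_0.SOL = 0.9130559637029425
l_0.TA = 1.4087239342511841
K_CP.GM = -12.522237100558232
K_CP.IL = -2.2977694706325487
K_CP.HM = -16.357932473672363
K_CP.BF = 14.341241246332515
K_CP.RF = -19.109284931375576
K_CP.VAS = -1.5803546186914446
K_CP.GAS = 5.910434238030469
K_CP.SOL = -17.808116226986602
K_CP.TA = 9.848873344402975
K_CV.GM = 4.821895123754494
K_CV.IL = -12.17780889115491
K_CV.HM = -16.78109757514675
K_CV.BF = -2.3419855071840203
K_CV.RF = -10.687382852257233
K_CV.VAS = -18.941631897369437
K_CV.GAS = 1.7956618627787613
K_CV.SOL = -7.52050186606353
K_CV.TA = 0.6410286639045495
K_F.0 = 2.5455492136419573
K_F.1 = 0.5110189178339337
K_F.2 = 0.39330646757134985
K_F.3 = 0.0
K_F.4 = 3.1122421724522846
K_F.5 = 2.0030787134280423
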