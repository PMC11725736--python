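response,eq_no,term,coefficient
DE,1,intercept,4045.0
DE,1,CF,-48.2
DE,1,UA,8962.9
DE,1,UA^2,-98096.6
DE,1,P,1117.0
DE,2,intercept,2670.2
DE,2,CF,-41.9
DE,2,UA,10364.0
DE,2,UA^2,-127507.0
DE,2,CP,49.5
DE,3,intercept,4156.8
DE,3,P,939.2
DE,3,NDF,-22.8
DE,3,UA,10159.4
DE,3,UA^2,-114950.0
DE,4,intercept,4719.9
DE,4,CF,-54.8
DE,4,UA,8018.9
DE,4,UA^2,-95188.1
DE,5,intercept,4474.9
DE,5,UA,8898.7
DE,5,UA^2,-109857.0
DE,6,intercept,5002.3
DE,6,CF,-98.2
ME,1,intercept,3060.2
ME,1,PS,16.3
ME,1,PP,-443.8
ME,1,UA,11516.7
ME,1,UA^2,-104776.0
ME,1,EAS,93.1
ME,2,intercept,1231.7
ME,2,PS,15.0
ME,2,UA,9730.0
ME,2,UA^2,-107594.0
ME,2,ASH,399.9
ME,2,CF,-58.8
ME,3,intercept,2676.3
ME,3,UA,12716.7
ME,3,UA^2,-139023.0
ME,3,ASH,325.3
ME,3,PP,-131.6
ME,4,intercept,1988.9
ME,4,UA,11979.4
ME,4,UA^2,-136049.0
ME,4,ASH,470.2
ME,4,CF,-43.7
ME,5,intercept,2166.4
ME,5,UA,13479.3
ME,5,UA^2,-154864.0
ME,5,ASH,396.5
ME,6,intercept,4269.5
ME,6,UA,13742.2
ME,6,UA^2,-157576.0
ME,7,intercept,4735.0
ME,7,PP,-266.8
ME,8,intercept,1854.8
ME,8,PS,31.8
MEn,1,intercept,2789.8
MEn,1,PS,18.1
MEn,1,PP,-431.5
MEn,1,UA,10240.6
MEn,1,UA^2,-92301.3
MEn,1,EAS,98.1
MEn,2,intercept,1277.3
MEn,2,PS,18.1
MEn,2,UA,8404.5
MEn,2,UA^2,-94031.1
MEn,2,ASH,319.34
MEn,2,CF,-51.0
MEn,3,intercept,2691.8
MEn,3,PS,20.5
MEn,3,PP,-164.3
MEn,3,UA,9010.3
MEn,3,UA^2,-93573.4
MEn,4,intercept,1787.0
MEn,4,PS,11.6
MEn,4,UA,10907.7
MEn,4,UA^2,-125536.0
MEn,4,ASH,274.9
MEn,5,intercept,2326.0
MEn,5,UA,12247.5
MEn,5,UA^2,-142526.0
MEn,5,ASH,349.2
MEn,6,intercept,2692.2
MEn,6,PS,18.5
MEn,6,UA,10266.9
MEn,6,UA^2,-117047.0
MEn,7,intercept,4178.4
MEn,7,UA,12479.1
MEn,7,UA^2,-144914.0
MEn,8,intercept,1688.2
MEn,8,PS,32.5
MEn,9,intercept,4594.2
MEn,9,PP,-239.7
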