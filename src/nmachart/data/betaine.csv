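sr,obs1_lo,obs1_hi,obs2_lo,obs2_hi,obs3_lo,obs3_hi,obs4_lo,obs4_hi
1,260.54,346.5,279.2,354.39,279.4,357.98,294.9,311.82
2,170.81,285.4,211.33,289.15,217.9,395.28,233.82,269.9
3,146.27,203.54,158.22,235.18,174.79,240.81,202.12,312.4
4,73.36,153.46,80.47,160.16,87.2,162.99,40.5,80.47
5,369.77,135.99,71.36,280.84,6.93,108.9,171.88,15.94
6,258.31,225.49,25.17,678.21,170.2,110.81,149.87,90.89
7,108.19,235.24,220.35,285.29,212.79,80.11,89.75,305.22
8,518.65,8.64,212.35,57.64,271.38,1.73,167.51,386.99
9,96.44,54.07,3.27,246.37,95.09,106.38,136.92,20.92
10,827.36,46.91,21.24,21.08,559.93,165.78,113.29,51.53
11,199.72,19.1,374.88,12.35,488.5,271.43,82.33,84.31
12,250.81,514.58,182.4,144.04,724.19,30.82,33.88,241.51
13,71.21,76.79,123.05,104.74,308.2,49.54,479.27,20.26
14,28.74,68.61,52.5,185.37,402.2,301.37,233.43,17.8
15,279.76,36.41,107.49,566.26,134.15,65.84,1402.57,120.33
16,164.63,244.98,101.44,8.97,264.02,6.6,80.55,29.34
17,60.41,4.18,200.01,3.19,424.25,35,172.37,173.8
18,798.93,149.07,25.37,3.67,20.11,151.65,1069.05,20.02
19,102.41,245.68,301.43,3.75,284.25,105.72,139.47,152.99
20,850.98,24.59,312.86,22.17,182.2,204.54,92.12,5.64
21,47.36,35.01,120.48,237.44,268.42,202.57,31.73,26.63
22,7.95,56.92,675.78,126.87,127.54,66.91,308.98,438.79
23,105.24,266.52,168.57,398.71,12.25,302.4,230.73,520.94
24,160.21,127.61,82.16,245.96,543.01,58.72,34.75,73.35
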