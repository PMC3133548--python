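subject,channel,start_s,end_s,features,accuracy_pct
1,3,9,15,mean;variance;skewness;kurtosis,91.7
2,2,5,15,mean;variance,79.2
3,3,9,15,variance;skewness;kurtosis,79.2
4,2,8,14,mean;variance,75.0
5,3,9,15,mean,75.0
6,3,7,15,mean;variance;skewness,91.7
7,1,8,14,skewness,70.8
8,2,7,12,mean;variance,75.0
9,1,5,15,mean;variance,83.3
10,3,5,15,variance;skewness;kurtosis,87.5
11,3,7,15,variance;kurtosis,87.5
12,2,11,15,mean;variance;skewness;kurtosis,79.2
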