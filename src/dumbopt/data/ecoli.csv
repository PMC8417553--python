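codon,amino_acid,usage_per_1000
AAA,K,33.6303
AAC,N,21.7195
AAG,K,10.3093
AAT,N,17.7159
ACA,T,7.1064
ACC,T,23.4211
ACG,T,14.4130
ACT,T,9.0081
AGA,R,2.1019
AGC,S,16.1145
AGG,R,1.2011
AGT,S,8.8079
ATA,I,4.2038
ATC,I,25.1226
ATG,M,27.9251
ATT,I,30.3273
CAA,Q,15.3138
CAC,H,9.7087
CAG,Q,28.8259
CAT,H,12.9116
CCA,P,8.4076
CCC,P,5.5050
CCG,P,23.2209
CCT,P,7.0063
CGA,R,3.6032
CGC,R,22.0198
CGG,R,5.4049
CGT,R,20.9188
CTA,L,3.9035
CTC,L,11.0099
CTG,L,52.6474
CTT,L,11.0099
GAA,E,39.4355
GAC,D,19.1172
GAG,E,17.8160
GAT,D,32.1289
GCA,A,20.1181
GCC,A,25.5230
GCG,A,33.6303
GCT,A,15.3138
GGA,G,8.0072
GGC,G,29.6267
GGG,G,11.1100
GGT,G,24.7223
GTA,V,10.8097
GTC,V,15.3138
GTG,V,26.4238
GTT,V,18.3165
TAA,*,2.0018
TAC,Y,12.2110
TAG,*,0.2002
TAT,Y,16.2146
TCA,S,7.1064
TCC,S,8.6077
TCG,S,8.9080
TCT,S,8.5077
TGA,*,1.0009
TGC,C,6.4058
TGG,W,15.2137
TGT,C,5.2047
TTA,L,13.9125
TTC,F,16.6150
TTG,L,13.7123
TTT,F,22.2200
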