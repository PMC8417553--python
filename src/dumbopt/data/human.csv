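codon,amino_acid,usage_per_1000
AAA,K,24.3951
AAC,N,19.0962
AAG,K,31.8936
AAT,N,16.9966
ACA,T,15.0970
ACC,T,18.8962
ACG,T,6.0988
ACT,T,13.0974
AGA,R,12.1976
AGC,S,19.4961
AGG,R,11.9976
AGT,S,12.0976
ATA,I,7.4985
ATC,I,20.7958
ATG,M,21.9956
ATT,I,15.9968
CAA,Q,12.2975
CAC,H,15.0970
CAG,Q,34.1932
CAT,H,10.8978
CCA,P,16.8966
CCC,P,19.7960
CCG,P,6.8986
CCT,P,17.4965
CGA,R,6.1988
CGC,R,10.3979
CGG,R,11.3977
CGT,R,4.4991
CTA,L,7.1986
CTC,L,19.5961
CTG,L,39.5921
CTT,L,13.1974
GAA,E,28.9942
GAC,D,25.0950
GAG,E,39.5921
GAT,D,21.7956
GCA,A,15.7968
GCC,A,27.6945
GCG,A,7.3985
GCT,A,18.3963
GGA,G,16.4967
GGC,G,22.1956
GGG,G,16.4967
GGT,G,10.7978
GTA,V,7.0986
GTC,V,14.4971
GTG,V,28.0944
GTT,V,10.9978
TAA,*,0.9998
TAC,Y,15.2969
TAG,*,0.7998
TAT,Y,12.1976
TCA,S,12.1976
TCC,S,17.6965
TCG,S,4.3991
TCT,S,15.1970
TGA,*,1.5997
TGC,C,12.5975
TGG,W,13.1974
TGT,C,10.5979
TTA,L,7.6985
TTC,F,20.2959
TTG,L,12.8974
TTT,F,17.5965
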