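group,region,marker,mean,sem,n,provenance
WT,SVZ,Ki67,1036,57,5,reported group summary (mean±SEM)
5xFAD,SVZ,Ki67,224,37,5,reported group summary (mean±SEM)
5xFAD+iACS,SVZ,Ki67,812,67,5,reported group summary (mean±SEM)
WT,SVZ,Nestin,273,28,5,reported group summary (mean±SEM)
5xFAD,SVZ,Nestin,96,10,5,reported group summary (mean±SEM)
5xFAD+iACS,SVZ,Nestin,154,22,5,reported group summary (mean±SEM)
WT,SVZ,DCX,873,71,5,reported group summary (mean±SEM)
5xFAD,SVZ,DCX,172,51,5,reported group summary (mean±SEM)
5xFAD+iACS,SVZ,DCX,454,39,5,reported group summary (mean±SEM)
WT,hippocampus,Ki67,403,43,5,reported group summary (mean±SEM)
5xFAD,hippocampus,Ki67,170,23,5,reported group summary (mean±SEM)
5xFAD+iACS,hippocampus,Ki67,293,27,5,reported group summary (mean±SEM)
WT,hippocampus,Nestin,1554,78,5,reported group summary (mean±SEM)
5xFAD,hippocampus,Nestin,241,24,5,reported group summary (mean±SEM)
5xFAD+iACS,hippocampus,Nestin,942,85,5,reported group summary (mean±SEM)
WT,hippocampus,DCX,1941,113,5,reported group summary (mean±SEM)
5xFAD,hippocampus,DCX,777,45,5,reported group summary (mean±SEM)
5xFAD+iACS,hippocampus,DCX,1510,157,5,reported group summary (mean±SEM)
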