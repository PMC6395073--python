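label,g_Na,g_CaT,g_CaS,g_A,g_KCa,g_Kd,g_H,g_leak,tau_ca,score
a,1076.392,6.4056,10.048,8.0384,17.584,124.0928,0.11304,0.17584,653.5,0.051
b,1165.568,6.6568,9.5456,54.5104,16.328,110.7792,0.0628,0.10676,813.88,0.053
c,1228.368,7.0336,11.0528,117.5616,16.328,111.2816,0.13816,0.10676,605.98,0.027
d,1203.248,6.6568,10.5504,59.5344,16.328,111.4072,0.0,0.10676,653.5,0.471
e,1210.784,8.164,6.28,113.04,12.56,118.4408,0.1256,0.0314,393.13,0.109
f,1245.952,7.7872,6.7824,84.6544,12.56,113.9192,0.02512,0.0,174.34,0.047
fig2,1228.368,7.0336,11.0528,117.5616,16.328,110.7792,0.13816,0.10048,605.98,0.007
fig3,895.528,3.8936,16.5792,116.4312,21.352,115.6776,0.0,0.08792,828.73,0.058
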