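sh3,prm,kd_molar,method,sd_molar,approx
SH3A,PRM1,500e-6,NMR,50e-6,true
SH3B,PRM1,300e-6,NMR,30e-6,true
SH3C,PRM1,600e-6,NMR,60e-6,true
SH3A,PRM2,3000e-6,NMR,400e-6,true
SH3B,PRM2,2000e-6,NMR,300e-6,true
SH3C,PRM2,4000e-6,NMR,500e-6,false
SH3A,PRM3,800e-6,NMR,80e-6,true
SH3B,PRM3,500e-6,NMR,50e-6,true
SH3C,PRM3,1000e-6,NMR,100e-6,true
SH3A,PRM4,60e-6,ITC,6e-6,true
SH3B,PRM4,6e-6,ITC,1e-6,false
SH3C,PRM4,12e-6,ITC,2e-6,true
SH3A,PRM5,150e-6,NMR,15e-6,true
SH3B,PRM5,40e-6,ITC,5e-6,true
SH3C,PRM5,100e-6,NMR,10e-6,true
SH3A,PRM6,200e-6,NMR,20e-6,true
SH3B,PRM6,60e-6,ITC,8e-6,true
SH3C,PRM6,150e-6,NMR,15e-6,true
SH3A,PRM1star,720e-6,NMR,20e-6,false
SH3B,PRM1star,1140e-6,NMR,50e-6,false
SH3C,PRM1star,210e-6,NMR,10e-6,false
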