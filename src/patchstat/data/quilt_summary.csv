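name,quilt_class,year,n_patches,height_cm,width_cm,overall_area_cm2,patched_area_cm2
R1,regular,ca. 1930,784,208.28,208.28,43381,15661
R2,regular,ca. 1930,440,203.2,175.26,35612,17934
R3,regular,1898,421,218.44,165.1,36064,18520
R4,regular,ca. 1930,327,215.9,209.55,45241,31877
R5,regular,1891,972,187.96,173.99,32703,32020
R6,regular,1890-1910,692,191.77,187.96,36045,19980
R7,regular,1890-1910,736,201.93,200.66,40519,25460
R8,regular,1900-1920,192,182.88,173.99,31819,25948
C1,crazy,ca. 1930,239,198.12,160.02,31703,21895
C2,crazy,1871,512,193.04,160.02,30890,21327
C3,crazy,1884,317,207.01,180.34,37332,35757
C4,crazy,1885,834,195.58,162.56,31793,31793
C5,crazy,ca. 1875,108,35.56,35.56,1265,1203
C6,crazy,ca. 1890,322,139.7,200.02,27943,26636
C7,crazy,1880-1900,106,134.6,132.08,17778,17505
C8,crazy,ca. 1889,133,210.82,170.18,35877,34550
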