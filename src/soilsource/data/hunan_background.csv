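element,background,screening,source_label
As,12.80,40.00,national
Cd,0.14,0.30,national
Cr,150.00,150.00,national
Cu,25.00,50.00,national
Ni,27.80,60.00,national
Pb,30.00,70.00,national
Zn,84.20,200.00,national
Ca,1300.00,,national
Mg,4000.00,,national
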