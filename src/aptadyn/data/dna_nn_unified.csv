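kind,key,dg37,dh,ds
stack,AA/TT,-1.00,-7.9,-22.2
stack,AT/AT,-0.88,-7.2,-20.4
stack,TA/TA,-0.58,-7.2,-21.3
stack,CA/GT,-1.45,-8.5,-22.7
stack,GT/CA,-1.44,-8.4,-22.4
stack,CT/GA,-1.28,-7.8,-21.0
stack,GA/CT,-1.30,-8.2,-22.2
stack,CG/CG,-2.17,-10.6,-27.2
stack,GC/GC,-2.24,-9.8,-24.4
stack,GG/CC,-1.84,-8.0,-19.9
terminal_at,AT,0.05,2.2,6.9
hairpin,3,3.5,,
hairpin,4,3.5,,
hairpin,5,3.6,,
hairpin,6,4.0,,
hairpin,7,4.1,,
hairpin,8,4.1,,
hairpin,9,4.2,,
hairpin,10,4.3,,
hairpin,12,4.5,,
hairpin,14,4.6,,
hairpin,16,4.7,,
hairpin,18,4.8,,
hairpin,20,4.9,,
hairpin,25,5.2,,
hairpin,30,5.4,,
bulge,1,4.0,,
bulge,2,2.9,,
bulge,3,3.1,,
bulge,4,3.2,,
bulge,5,3.3,,
bulge,6,3.5,,
bulge,7,3.7,,
bulge,8,3.9,,
bulge,9,4.1,,
bulge,10,4.3,,
bulge,12,4.5,,
bulge,14,4.8,,
bulge,16,5.0,,
bulge,18,5.2,,
bulge,20,5.3,,
bulge,25,5.6,,
bulge,30,5.9,,
internal,3,3.2,,
internal,4,3.6,,
internal,5,4.0,,
internal,6,4.4,,
internal,7,4.6,,
internal,8,4.8,,
internal,9,4.9,,
internal,10,4.9,,
internal,12,5.2,,
internal,14,5.4,,
internal,16,5.6,,
internal,18,5.8,,
internal,20,5.9,,
internal,25,6.3,,
internal,30,6.6,,
multi_a,,4.6,,
multi_b,,0.4,,
multi_c,,0.1,,
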