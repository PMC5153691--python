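# Abbreviations that must never end a sentence at the splitter.
sp.
spp.
subsp.
e.g.
i.e.
approx.
ca.
cf.
var.
temp.
al.
vs.
viz.
str.
gen.
nov.
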