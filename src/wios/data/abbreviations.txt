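# Period-final tokens that never end a sentence (case-insensitive).
dr.
mr.
mrs.
ms.
prof.
st.
jr.
sr.
rev.
gen.
gov.
sen.
rep.
hon.
capt.
col.
lt.
sgt.
vs.
etc.
eg.
e.g.
ie.
i.e.
cf.
approx.
dept.
univ.
inst.
assn.
bros.
co.
corp.
inc.
ltd.
no.
nos.
vol.
pp.
fig.
figs.
jan.
feb.
mar.
apr.
jun.
jul.
aug.
sep.
sept.
oct.
nov.
dec.
mon.
tue.
wed.
thu.
fri.
sat.
sun.
u.s.
u.k.
u.n.
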