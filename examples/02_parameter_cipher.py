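"""Walk the parameter cipher through its published example, printing each stage.

The security parameters "12,3.78,0.51,3.92,0.44" (key0 plus two logistic
pairs) are confused under key1=4, key2=7, Pk=1 via a simulated
DNA -> mRNA -> tRNA/rRNA flow and an Arnold-scrambled amino-acid digram
table; the confounding parameters "4,7,1" go through the unscrambled table.
"""

import numpy as np

from dnaotp import params

tr = params.security_confusion_trace("12,3.78,0.51,3.92,0.44", key1=4, key2=7, pk=1)
print("ASCII bits   :", tr.bits[:32], f"... ({len(tr.bits)} bits)")
print("DNA (key1=4) :", tr.dna[:32], f"... ({len(tr.dna)} nt)")
print("tRNA half    :", tr.trna)
print("rRNA half    :", tr.rrna)
print("M coords     :", " ".join(map(str, tr.m_values)))
print("N coords     :", " ".join(map(str, tr.n_values)))
print("digrams A0   :", " ".join(tr.digrams))

rng = np.random.default_rng(0)
sp = params.SecurityParams.parse("12,3.78,0.51,3.92,0.44")
cp = params.ConfoundingParams(4, 7, 1)
c0 = params.confuse_security(sp, cp, rng)
c1 = params.encrypt_confounding(cp, rng)
print("C0 (chaffed) :", c0)
print("C1 (chaffed) :", c1)

# receiver side: C1 first (initial table), then C0 with the recovered Pk/keys
cp_rec = params.decrypt_confounding(c1)
sp_rec = params.decrypt_security(c0, cp_rec)
print("recovered    :", sp_rec.serialize(), "/", cp_rec.serialize())
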