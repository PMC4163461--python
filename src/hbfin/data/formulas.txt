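# Bundled knowledge base: function formulas in the ASCII predicate-logic
# dialect, one universally quantified implication per line.
# Literal suffixes a/b/c refer to condition-table bands; a literal without
# a suffix names another formula's consequent (an intermediate hypothesis).
forall p. SPa(p) & MDPa(p) & MAPa(p) & DPa(p) -> HT(p)
forall p. BVa(p) -> Low_BV(p)
forall p. MAPb(p) & SPb(p) & Low_BV(p) -> HPT(p)
forall p. PRa(p) -> TC(p)
forall p. PRb(p) -> BC(p)
forall p. SVa(p) & SIa(p) -> Low_BE(p)
forall p. SVb(p) & SIb(p) -> High_BE(p)
forall p. VPEa(p) & CIa(p) -> Low_CPP(p)
forall p. VPEb(p) -> High_CPP(p)
forall p. Ya(p) & Yra(p) -> HV(p)
forall p. Yb(p) & Yrb(p) -> HPV(p)
forall p. ACa(p) & FEKa(p) & Wta(p) & BLKa(p) & SVb(p) & HV(p) -> Dyn_HV(p)
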