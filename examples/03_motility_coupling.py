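"""Ca2+-sensitivity coupling from in vitro motility curves.

Generates paired phosphorylated/unphosphorylated activation curves at
the native thin-filament condition (EC50 0.059 uM unphosphorylated,
2.24-fold desensitisation on phosphorylation), refits the Hill model
and makes the coupling call.  A mean P/unP EC50 ratio above 1.5 with a
significant paired test means phosphorylation still modulates Ca2+
sensitivity - the coupled phenotype.
"""

from tncoupling.motility import coupling_call, fit_hill
from tncoupling.synthetic import CurveSpec, gen_activation_curves

pairs, _ = gen_activation_curves(
    CurveSpec(ec50_unp_um=0.059, ratio=2.24, noise_sd=0.03, n_replicates=6, seed=3)
)
fits = [(fit_hill(p), fit_hill(u)) for p, u in pairs]
call = coupling_call(fits)

print(f"EC50 (P)   : {fits[0][0].ec50:.3f} uM   EC50 (unP): {fits[0][1].ec50:.3f} uM")
print(f"mean ratio : {call.mean_ratio:.2f} +/- {call.sem_ratio:.2f} "
      f"(n={len(call.ratios)}, p={call.p_value:.2g})")
print(f"coupled    : {call.coupled}")
print("A ratio near 2.24 reproduces the native 2-3 fold desensitisation;")
print("uncoupling mutations push the ratio to ~1 and the call to False.")
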