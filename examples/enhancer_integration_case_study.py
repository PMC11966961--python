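"""Enhancer switching and the additive-vs-competitive integration case study.

Each gene reads a dynamic enhancer (sequence-driving, morphogen-activated)
and a static enhancer (pattern-stabilizing, morphogen-repressed).  The two
activities can sum at the gene (additive) or compete for the promoter,
which caps production at the promoter rate k_t.  The cap is what buffers
the pattern against an overactive enhancer.
"""

from morphogrn import (
    EnhancerPerturbation,
    EnhancerSwitchSpec,
    GradientSpec,
    Tissue1D,
    mismatch_score,
    run_enhancer_switching,
    segment_domains,
)

tissue = Tissue1D(100)
gradient = GradientSpec(form="static_sigmoid", k=-0.2, x0=50.0)

wt_add = segment_domains(
    run_enhancer_switching(tissue, gradient, EnhancerSwitchSpec(), t_end=120.0)
)
print("wild-type additive pattern:", wt_add.domains)

# robustness: any single 2-fold parameter change barely moves the pattern
base = EnhancerSwitchSpec()
for param in ("theta_s", "lam", "k_ts", "k_td"):
    for fold in (0.5, 2.0):
        spec = EnhancerSwitchSpec(**{param: getattr(base, param) * fold})
        m = mismatch_score(
            wt_add,
            segment_domains(run_enhancer_switching(tissue, gradient, spec, t_end=120.0)),
        )
        print(f"  {param} x{fold}: mismatch {m:.2f}")
print("  -> at most 10-20% of cells change identity: the pattern is robust")

# case study: 10x overactive dynamic enhancer on gene 3
pert = EnhancerPerturbation(gene_index=3, enhancer="dynamic", factor=10.0)
mut_add = segment_domains(
    run_enhancer_switching(
        tissue, gradient, EnhancerSwitchSpec(perturbation=pert), t_end=120.0
    )
)
wt_comp = segment_domains(
    run_enhancer_switching(
        tissue, gradient, EnhancerSwitchSpec(integration="competitive"), t_end=120.0
    )
)
mut_comp = segment_domains(
    run_enhancer_switching(
        tissue,
        gradient,
        EnhancerSwitchSpec(integration="competitive", perturbation=pert),
        t_end=120.0,
    )
)
print(f"additive integration, overactive enhancer: "
      f"mismatch {mismatch_score(wt_add, mut_add):.2f}")
print(f"competitive integration, same perturbation: "
      f"mismatch {mismatch_score(wt_comp, mut_comp):.2f}")
print("  -> promoter competition normalizes the rogue enhancer's output,"
      " preserving the pattern")
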