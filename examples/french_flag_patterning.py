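"""French Flag realizations: threshold readouts of morphogen gradients.

Runs the four gradient-interpretation circuits on a 100-cell tissue and
prints the expression domains each produces.
"""

from morphogrn import (
    GradientSpec,
    Tissue1D,
    run_additive_stripe_enhancers,
    run_french_flag_thresholds,
    run_nested_feedforward,
    run_two_gradient_model,
    segment_domains,
)

tissue = Tissue1D(100)
gradient = GradientSpec(form="static_sigmoid", k=-0.1, x0=50.0)  # high at x=0

field = run_french_flag_thresholds(tissue, gradient)
summary = segment_domains(field, threshold_mode="half_max")
print("threshold readout domains:", summary.domains)
print("  -> activated genes extend from the high-M end to where M crosses their K;"
      " repressed genes occupy the complement")

field = run_two_gradient_model(tissue)
summary = segment_domains(field, threshold_mode="half_max")
print("two-gradient domains:", summary.domains)
print("  -> two opposing repressive gradients carve interior, mirror-image domains")

field = run_nested_feedforward(tissue, gradient)
summary = segment_domains(field, threshold_mode="argmax")
print("nested feed-forward domains:", summary.domains)
print("  -> cross-repression refines one gradient into abutting ordered domains")

field = run_additive_stripe_enhancers(tissue)
summary = segment_domains(field, threshold_mode="half_max")
print("additive enhancer domains:", [d for d in summary.domains if d[0] == "G"])
print("  -> one stripe per enhancer; the gene reads their summed activity")
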