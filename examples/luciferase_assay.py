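"""Dual-luciferase reporter normalization and construct comparison.

Simulates three independent transfection experiments for AT- and G-allele
promoter constructs against the empty-vector control, normalizes firefly by
Renilla luminescence per well, expresses activity relative to the control
within each experiment, and compares constructs across experiments.
"""

from asekit import simulate_reporter_wells, summarize_assay

wells = simulate_reporter_wells({"AT-insert": 1.8, "G-insert": 0.95}, seed=42)
for s in summarize_assay(wells):
    print(f"{s.construct:>9}: relative activity {s.mean_relative_activity:.3f} "
          f"+/- {s.sd:.3f} (n={s.n_experiments} experiments), "
          f"p vs control = {s.p_vs_control:.4f}")
# Relative activity 1.0 means "same as the empty vector".  The AT construct
# drives ~1.8x the control and reaches significance; the G construct's
# slight deficit does not, mirroring an assay where only the AT allele
# measurably boosts transcription.
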