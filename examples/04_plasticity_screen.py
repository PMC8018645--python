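"""Amplitude-based plasticity screen with Pearson residuals.

The amplitude of a (variety, compound) pair is the range of its block
means across environments (on z-scaled means so units cancel).  Treating
the amplitude table like a contingency table gives expected amplitudes
E = Sci*Srj/St and residuals r = (A-E)/sqrt(E); compounds with a large
summed |r| show a strong *differential* of plasticity between varieties.
"""

from metaplast.core import block_means
from metaplast.plasticity import amplitudes, expected_amplitudes, screen_compounds
from metaplast.simulate import CompoundSpec, SimSpec, simulate_panel

comps = [CompoundSpec(f"flat{i}", mu=10, sigma_g=0.5, sigma_e=1.0, sigma_resid=0.25)
         for i in range(7)]
comps.append(CompoundSpec("hot", mu=10, sigma_g=0.5, sigma_e=1.0,
                          sigma_gxe=1.0, sigma_resid=0.25))
spec = SimSpec(n_varieties=5, n_locations=10, n_years=2, n_blocks=3,
               compounds=comps, seed=5)
table, _ = simulate_panel(spec)

amp = amplitudes(block_means(table), scale_mode="zscore")
tab = expected_amplitudes(amp)
summary = screen_compounds(tab.residuals, rule="median")
print(summary.round(3))
# 'hot' carries a real genotype-by-environment interaction, so its
# varieties' amplitudes deviate most from the margin-product expectation
# and its |residual| sum tops the table, clearing the (strict) median
# cutoff; interaction-free compounds hover near it by chance alone.
print("\nselected for stability analysis:", list(summary.index[summary["selected"]]))
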