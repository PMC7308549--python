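"""The non-linear relationship between expression rate and heterogeneity.

Sweeps the global PR positivity of patchy simulated tumors from 2% to 98%
and records the co-occurrence entropy of each map. Entropy is necessarily
low at the extremes (nearly all hexagons fall in the bottom or top decile
bin) and peaks in the moderate-expression range — the reason moderate
expressors can form a distinct prognostic group.
"""

from hexiht import ScenarioSpec, positivity_sweep

template = ScenarioSpec(width_mm=5, height_mm=5, tumor_intensity=1200)
sweep = positivity_sweep(
    template, [0.02, 0.1, 0.2, 0.35, 0.5, 0.65, 0.8, 0.9, 0.98], seed=3
)
print(sweep.to_string(index=False,
                      formatters={"p_global": "{:.0f}".format,
                                  "entropy": "{:.3f}".format,
                                  "ashman_d": "{:.2f}".format}))
peak = sweep.loc[sweep.entropy.idxmax()]
print(f"\nentropy peaks at {peak.p_global:.0f}% global positivity "
      f"(entropy {peak.entropy:.3f}); the curve is near zero at 2% and 98%.")
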