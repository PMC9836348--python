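"""Simulate a chemogenomic SGA screen with known ground truth.

Generates 500 library genes (10% planted suppressors with interaction
ratio rho <= 0.3, 10% enhancers with rho >= 1.7), lays them out on
384-format plates with scattered WT/query control positions, replica-pins
each plate 16 times, and simulates colony sizes for all four strain
classes in rich medium (YPD) and under drug.
"""

import sgascreen as sga

truth = sga.generate_truth(500, frac_suppressor=0.1, frac_enhancer=0.1,
                           suppressor_high=0.3, enhancer_low=1.7, seed=1)
layouts = sga.layout_plates(truth, controls_per_plate=16, seed=1)
replicas = sga.replicate_layouts(layouts, 16)
colonies = sga.simulate_screen(truth, replicas, sga.ArtifactParams.realistic(),
                               seed=1)

classes = {c: sum(v == c for v in truth.gene_class.values())
           for c in ("suppressor", "enhancer", "neutral")}
print(f"planted classes: {classes}")
print(f"{len(layouts)} layout plates x 16 replicas = {len(replicas)} plates")
print(f"colony table: {len(colonies)} measurements "
      f"({colonies['missing'].sum()} missing)")
dko = colonies[(colonies.strain_class == 'DKO') & (colonies.condition == 'DRUG')]
print(f"median DKO colony size under drug: {dko[~dko.missing]['size'].median():.0f} px")
# The DKO/DRUG median reflects the query's drug resistance multiplier (2x)
# times the 300 px baseline, modulated by plate artifacts and noise.
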