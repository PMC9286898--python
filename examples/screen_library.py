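"""Screen a compound library against a disease panel.

Trains a quick model on a synthetic benchmark, then (1) filters the library
to QC / blood-detectable / OB>30% compounds, (2) enumerates unknown pairs,
(3) scores and ranks them, and (4) flags candidates above the 0.9 cut.
"""

from cdrscreen import (
    ScreenConfig, SimConfig, SplitSpec, TrainConfig,
    enumerate_unknown_pairs, filter_compounds, screen, simulate,
)
from cdrscreen.dataset import complement_pool, make_ratio_datasets
from cdrscreen.pipeline import normalize_world, run_experiment

world = simulate(SimConfig(n_compounds=120, n_diseases=24, seed=11))
positives = world.positive_pairs
pool = complement_pool(world.compounds.ids, world.diseases.ids, positives)
spec = SplitSpec(ratio_neg_per_pos=1, sample_size=800, repeats=1, seed=11)
split = make_ratio_datasets(positives, pool, spec)[0]
result = run_experiment(world, split, TrainConfig.desk_scale(seed=11, max_epochs=10))

config = ScreenConfig(ob_threshold=30.0, candidate_cut=0.9)
kept = filter_compounds(world.compounds, config)
pairs = enumerate_unknown_pairs(
    [r.compound_id for r in kept], world.diseases.ids, positives
)
compounds, diseases = normalize_world(world)
screened = screen(result.trained, pairs, compounds, diseases, config)

print(f"library: {len(world.compounds)} compounds -> {len(kept)} pass the "
      f"QC/blood/OB>30% filter")
print(f"unknown pairs scored: {screened.summary['n_pairs']}")
print(f"predicted positive (p > 0.5): {screened.summary['n_predicted_positive']}")
print(f"candidates (p > 0.9):         {screened.summary['n_candidates']}")
print("\ntop 5 ranked pairs:")
print(screened.entries.head(5).to_string(index=False))
# Candidates are compound-disease pairs the model is most confident about;
# in a real screen these go forward to literature and assay verification.
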