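"""Full sweep: classification accuracy as a function of channel count.

For each selection method, rank channels once, then evaluate the top-k
subset for k = 1..8 with TD features and LDA.  MCCSP/FMS subsets are scored
by stratified 5-fold cross-validation, SFS by its half/half temporal
holdout.  The curves should rise steeply until every planted channel is
included and then plateau.
"""

from emgpick import ExperimentConfig, channel_distribution_report, compute_rankings, run_channel_curve
from emgpick.synth import SynthConfig

synth = SynthConfig(
    n_classes=8,
    n_channels=16,
    gain=5.0,
    informative_map={c: frozenset({2 * c}) for c in range(8)},
    seed=3,
)
config = ExperimentConfig(
    methods=("MCCSP", "SFS", "FMS"),
    feature_sets=("td",),
    classifiers=("lda",),
    k_range=tuple(range(1, 9)),
    synth=synth,
    seed=3,
    sfs_max_k=8,
    apply_preprocessing=False,  # generator output is already band-limited
)
rankings = compute_rankings(config)
table = run_channel_curve(config, rankings=rankings)
print(table.pivot(index="k", columns="method", values="accuracy_pct").round(2))
# Rows are channel counts; accuracy climbs to ~100% once all 8 planted
# channels are included, for every method.

report = channel_distribution_report(rankings)
print("\nMCCSP set fixed across feature/classifier combinations:",
      report["MCCSP"]["fixed_across_combinations"])
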