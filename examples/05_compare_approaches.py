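"""Run a small end-to-end experiment and compare approaches statistically.

A desk-scale cohort is generated, the AD task is matched and split twice,
and three approaches are evaluated: the brain age gap (BAG), a logistic
ridge on brain-age features (Brainage64D), and a from-scratch classifier
(Direct).  Summaries use the corrected resampled t-test with FDR flags.
Expect a couple of minutes on one CPU.
"""

import pandas as pd

from braingap.orchestration import run_experiment

config = {
    "seed": 7,
    "k": 2,
    "generator": {
        "volume_shape": [16, 20, 16],
        "n_per_group": {"CN": 16, "AD": 16, "sMCI": 0, "pMCI": 0},
        "datasets": [["D1", ["s1"]]],
        "overlap_rho": 0.0,
        "disease_amplitude": 120.0,
    },
    "pretrain_generator": {
        "n_per_group": {"CN": 32, "AD": 0, "sMCI": 0, "pMCI": 0},
        "datasets": [["PRE", ["p1"]]],
    },
    "model": {"filters": [4, 8, 8], "input_shape": [16, 20, 16], "dropout_rate": 0.25},
    "train": {"initial_lr": 0.1, "epochs": 8, "batch_size": 8},
    "finetune": {"initial_lr": 0.1, "epochs": 6, "batch_size": 8,
                 "update_bn_stats": False},
    "pretrain": {"initial_lr": 0.05, "epochs": 15, "batch_size": 8,
                 "lr_decay_every": 12},
    "tasks": {"AD_CN": ["bag", "brainage64d", "direct"], "MCI_PROG": []},
}

out = run_experiment(config, "scratch/example_experiment")
desc = pd.read_csv(out / "descriptives.tsv", sep="\t")
comp = pd.read_csv(out / "comparisons.tsv", sep="\t")
print("\nTest AUC (mean +/- sd over repetitions):")
for _, row in desc.iterrows():
    print(f"  {row['approach']:>12}: {row['mean_auc']:.3f} +/- {row['std_auc']:.3f}")
print("\nPairwise corrected resampled t-tests:")
for _, row in comp.iterrows():
    print(f"  {row['approach_a']} vs {row['approach_b']}: "
          f"diff {row['mean_diff']:+.3f}, t = {row['t']:.2f}, p = {row['p']:.3f}")
# With an orthogonal disease pattern BAG hovers near chance (0.5) while the
# directly trained classifier exploits the disease pattern; with only k=2
# repetitions the corrected test is deliberately conservative.
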