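"""Build the SFCN, count its parameters, and pretrain a small brain-age model.

The reference-scale backbone ([32,64,128,256,256,64] filters, 167x212x160
input) has 2,950,466 trainable parameters with the 2-class head and
2,950,401 with the 1-output regression head; the global-average-pooling
feature vector has length 64.  The desk-scale preset exercises the same
code on CPU-sized volumes.
"""

import dataclasses

import numpy as np

from braingap.preprocess import normalize_intensity
from braingap.sfcn import (
    DESK_FILTERS,
    HEAD_REGRESSION,
    REFERENCE_FILTERS,
    SFCNConfig,
    TrainConfig,
    build_sfcn,
    count_trainable_parameters,
    extract_features,
    pretrain_brainage,
)
from braingap.synthetic_data import GeneratorConfig, generate_cohort

ref = SFCNConfig(filters=REFERENCE_FILTERS, input_shape=(167, 212, 160))
print("reference scale:")
print(f"  classification head: {count_trainable_parameters(build_sfcn(ref)):,} parameters")
reg = dataclasses.replace(ref, head=HEAD_REGRESSION)
print(f"  regression head:     {count_trainable_parameters(build_sfcn(reg)):,} parameters")
print(f"  feature map after 5 poolings: {ref.feature_map_shape()} -> "
      f"{ref.feature_length} pooled features")

# desk-scale brain-age pretraining on a healthy synthetic cohort
cfg = GeneratorConfig(volume_shape=(12, 14, 12),
                      n_per_group={"CN": 80, "AD": 0, "sMCI": 0, "pMCI": 0},
                      datasets=(("PRE", ("p1",)),),
                      age_amplitude=15.0, aging_variability_sd=0.0,
                      noise_sd=2.0, site_offset_sd=0.0, site_gain_sd=0.0, seed=17)
records, vols = generate_cohort(cfg)
x = {k: normalize_intensity(v) for k, v in vols.items()}
model_cfg = SFCNConfig(filters=(4, 8), input_shape=(12, 14, 12),
                       head=HEAD_REGRESSION, dropout_rate=0.25)
model, trace = pretrain_brainage(
    model_cfg, records, x,
    TrainConfig(initial_lr=0.1, epochs=50, batch_size=8, lr_decay_every=40, seed=0))
ages = np.array([r.age for r in records])
const = np.abs(ages - ages.mean()).mean()
print(f"\ndesk pretraining: best validation MAE "
      f"{trace.attrs['best_metric']:.2f} y at epoch {trace.attrs['best_epoch']} "
      f"(constant-age predictor: {const:.2f} y)")
# An MAE well below the constant predictor means the model reads the aging
# pattern; its GAP features are what the transfer approaches reuse.
fv = extract_features(model, x[records[0].subject_id], records[0].subject_id)
print(f"feature vector for {fv.subject_id}: length {len(fv.values)}")
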